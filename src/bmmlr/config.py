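"""YAML/JSON run-configuration loading with explicit, field-path errors."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .model import ModelSpec, PriorSpec
from .effects import PopulationSpec
from .decisions import DecisionRule

__all__ = ["load_config", "config_hash", "ConfigError",
           "prior_from_config", "model_spec_from_config",
           "population_from_config", "rule_from_config"]


class ConfigError(ValueError):
    """A configuration schema violation, reported with its field path."""


def _require(cfg: dict, path: str, key: str, types=None):
    if key not in cfg:
        raise ConfigError(f"missing required field '{path}.{key}'")
    val = cfg[key]
    if types is not None and not isinstance(val, types):
        raise ConfigError(
            f"field '{path}.{key}' has type {type(val).__name__}, expected "
            + "/".join(t.__name__ for t in (types if isinstance(types, tuple) else (types,)))
        )
    return val


def load_config(path) -> dict:
    """Read and validate a run configuration (YAML or JSON)."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    if "data" in cfg:
        d = cfg["data"]
        _require(d, "data", "outcomes", list)
        if not d["outcomes"]:
            raise ConfigError("field 'data.outcomes' must name at least one column")
        _require(d, "data", "cluster", str)
        _require(d, "data", "treatment", str)
        d.setdefault("covariates", [])
        d.setdefault("interactions", True)
    if "model" in cfg:
        m = cfg["model"]
        t = _require(m, "model", "type", str)
        if t not in ("BMMLR", "BMLR", "BMB"):
            raise ConfigError(f"field 'model.type' must be BMMLR/BMLR/BMB, got '{t}'")
    mc = cfg.setdefault("mcmc", {})
    mc.setdefault("L", 2000)
    mc.setdefault("burnin", 500)
    mc.setdefault("chains", 2)
    mc.setdefault("thin", 1)
    mc.setdefault("seed", 0)
    for key in ("L", "burnin", "chains", "thin", "seed"):
        if not isinstance(mc[key], int):
            raise ConfigError(f"field 'mcmc.{key}' must be an integer")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a configuration (carried in outputs)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def prior_from_config(cfg: dict) -> PriorSpec:
    p = cfg.get("prior", {})
    allowed = {"coef_mean", "coef_var", "sigma_df", "sigma_scale",
               "improper_sigma", "dirichlet_alpha"}
    unknown = set(p) - allowed
    if unknown:
        raise ConfigError(f"unknown field(s) in 'prior': {sorted(unknown)}")
    return PriorSpec(**p)


def model_spec_from_config(cfg: dict, K: int, P: int) -> ModelSpec:
    m = cfg.get("model", {"type": "BMMLR"})
    mtype = m.get("type", "BMMLR")
    random_idx = tuple(m.get("random", (0, 1) if mtype == "BMMLR" else ()))
    fixed_idx = tuple(m.get("fixed", [i for i in range(P) if i not in random_idx]))
    for i in (*random_idx, *fixed_idx):
        if not 0 <= i < P:
            raise ConfigError(f"field 'model.random/fixed': column index {i} out of range for P={P}")
    return ModelSpec(mtype, K, random_idx, fixed_idx)


def population_from_config(cfg: dict, covariate_names: list[str], P: int) -> PopulationSpec:
    p = cfg.get("population", {"kind": "full"})
    kind = p.get("kind", "full")
    if kind == "full":
        return PopulationSpec.full(p.get("label", "full"))
    if kind == "interval":
        cov = _require(p, "population", "covariate", str)
        if cov not in covariate_names:
            raise ConfigError(
                f"field 'population.covariate': column '{cov}' not in design "
                f"({covariate_names})"
            )
        return PopulationSpec.interval(
            covariate_names.index(cov),
            float(p.get("lower", -np.inf)),
            float(p.get("upper", np.inf)),
            label=p.get("label", ""),
        )
    if kind == "value":
        vals = _require(p, "population", "values", list)
        return PopulationSpec.at_value(
            vals, P, interactions=bool(p.get("interactions", True)),
            label=p.get("label", ""),
        )
    raise ConfigError(f"field 'population.kind' must be full/interval/value, got '{kind}'")


def rule_from_config(cfg: dict) -> DecisionRule:
    d = cfg.get("decision", {"rule": "Compensatory", "weights": [0.5, 0.5]})
    rule = d.get("rule", "Compensatory")
    weights = d.get("weights")
    return DecisionRule(
        rule=rule,
        weights=tuple(weights) if weights is not None else None,
        alpha=float(d.get("alpha", 0.05)),
        sided=int(d.get("sided", 1)),
        primary=int(d.get("primary", 0)),
    )
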