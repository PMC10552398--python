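"""Persistence for chains, effect draws and decision reports.

Chain dumps pair a compact ``.npz`` (bit-exact round trip, consumed by the
transformation step) with optional per-block, per-chain CSVs for
inspection.  Effect draws and decision reports are plain CSV / JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec, PosteriorDraws, PriorSpec
from .joint_response import build_joint_response_space
from .effects import EffectDraws, PopulationSpec
from .decisions import DecisionResult

__all__ = [
    "save_draws",
    "load_draws",
    "export_chain_csvs",
    "save_effects",
    "load_effects",
    "decision_report",
]

_BLOCKS = ("beta", "gamma_j", "gamma_mean", "sigma")


def save_draws(draws: PosteriorDraws, path) -> None:
    """Write a posterior-draw dump (.npz plus a JSON metadata sidecar)."""
    path = Path(path)
    np.savez_compressed(path, **{b: getattr(draws, b) for b in _BLOCKS})
    meta = {
        "model": draws.spec.model,
        "K": draws.spec.K,
        "random_idx": list(draws.random_idx),
        "fixed_idx": list(draws.fixed_idx),
        "L": draws.L,
        "burnin": draws.burnin,
        "seed": draws.seed,
        "prior": vars(draws.prior).copy(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_draws(path) -> PosteriorDraws:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrs = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    spec = ModelSpec(
        meta["model"],
        meta["K"],
        tuple(meta["random_idx"]),
        tuple(meta["fixed_idx"]),
    )
    return PosteriorDraws(
        spec=spec,
        prior=PriorSpec(**meta["prior"]),
        space=build_joint_response_space(meta["K"]),
        beta=arrs["beta"],
        gamma_j=arrs["gamma_j"],
        gamma_mean=arrs["gamma_mean"],
        sigma=arrs["sigma"],
        L=meta["L"],
        burnin=meta["burnin"],
        seed=meta["seed"],
        random_idx=tuple(meta["random_idx"]),
        fixed_idx=tuple(meta["fixed_idx"]),
    )


def export_chain_csvs(draws: PosteriorDraws, outdir) -> list[Path]:
    """One CSV per parameter block per chain, columns flattened and named."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for block in _BLOCKS:
        arr = getattr(draws, block)
        if arr.size == 0:
            continue
        for c in range(arr.shape[0]):
            flat = arr[c].reshape(arr.shape[1], -1)
            idx = np.stack(
                np.unravel_index(np.arange(flat.shape[1]), arr.shape[2:])
            )
            cols = ["_".join(map(str, tup)) for tup in idx.T]
            df = pd.DataFrame(flat, columns=[f"{block}_{c_}" for c_ in cols])
            p = outdir / f"{block}_chain{c + 1}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    return written


def save_effects(effects: EffectDraws, path) -> None:
    effects.to_dataframe().to_csv(path, index=False)


def load_effects(path, weights=None, population: PopulationSpec | None = None) -> EffectDraws:
    df = pd.read_csv(path)
    delta_cols = [c for c in df.columns if c.startswith("delta_") and c != "delta_w"]
    delta = df[delta_cols].to_numpy(float)
    K = delta.shape[1]
    w = np.asarray(weights, dtype=float) if weights is not None else np.full(K, 1.0 / K)
    w = w / w.sum()
    return EffectDraws(
        delta=delta,
        delta_w=df["delta_w"].to_numpy(float),
        theta_treated=np.full_like(delta, np.nan),
        theta_control=np.full_like(delta, np.nan),
        weights=w,
        population=population or PopulationSpec.full(),
        outcome_names=[c.removeprefix("delta_") for c in delta_cols],
    )


def decision_report(results: dict[str, DecisionResult], meta: dict | None = None) -> dict:
    """JSON-serializable report of decisions keyed by label."""
    out = {"meta": meta or {}}
    for label, res in results.items():
        prob = res.posterior_prob
        out[label] = {
            "rule": res.rule.rule,
            "alpha": res.rule.alpha,
            "sided": res.rule.sided,
            "p_cut": res.p_cut,
            "posterior_prob": prob.tolist() if isinstance(prob, np.ndarray) else prob,
            "conclusion": res.conclusion,
        }
    return out
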