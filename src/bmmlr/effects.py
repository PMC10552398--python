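"""From posterior coefficients to (conditional) average treatment effects.

For each retained posterior draw the pipeline is:

1. evaluate every reference subject's joint response probabilities ``phi``
   under their own arm and cluster (``subject_joint_probs``),
2. average ``phi`` within each cluster-arm cell over the subjects that
   belong to the (sub)population of interest,
3. convert to marginal success probabilities and difference the arms per
   cluster (``cluster_effects``),
4. pool clusters weighted by their contributing sample sizes
   (``pool_clusters``), and
5. collapse the K-variate difference to a scalar with importance weights
   (``compensatory``).

Subpopulations are either the full reference sample, an interval of one
covariate (empirical averaging over the subjects inside it), or a single
covariate value (plugged straight into the linear predictor).  Averaging is
arm-restricted: each subject contributes only under the arm they were
observed in.  A counterfactual variant (evaluate everyone under both arms)
is available behind an explicit design-builder, switched off by default.

Cluster-arm cells left empty by interval filtering drop their cluster from
the pooled estimate; the weights renormalize over the remaining clusters.
Pooling weights count the subjects contributing to the population estimate
(both arms combined), not raw cluster size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .joint_response import JointResponseSpace, phi_to_theta, softmax_link
from .model import BmbDraws, PosteriorDraws
from .data import TrialDataset

__all__ = [
    "PopulationSpec",
    "EffectDraws",
    "linear_predictor",
    "subject_joint_probs",
    "cluster_effects",
    "pool_clusters",
    "compensatory",
    "transform_chain",
    "transform_bmb",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Which (sub)population a treatment effect refers to.

    ``kind``: ``"full"`` (whole reference sample), ``"interval"`` (subjects
    with ``lower <= x[:, covariate_col] <= upper``) or ``"value"`` (a single
    covariate profile, given as explicit per-arm design rows).
    """

    kind: str = "full"
    covariate_col: int | None = None
    lower: float = -np.inf
    upper: float = np.inf
    x_control: np.ndarray | None = None
    x_treated: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("full", "interval", "value"):
            raise ValueError(f"unknown population kind '{self.kind}'")
        if self.kind == "interval":
            if self.covariate_col is None:
                raise ValueError("interval population needs covariate_col")
            if not self.lower <= self.upper:
                raise ValueError("interval bounds must be ordered")
        if self.kind == "value" and (self.x_control is None or self.x_treated is None):
            raise ValueError("value population needs per-arm design rows")

    @classmethod
    def full(cls, label: str = "full") -> "PopulationSpec":
        return cls(kind="full", label=label)

    @classmethod
    def interval(
        cls, covariate_col: int, lower: float, upper: float, label: str = ""
    ) -> "PopulationSpec":
        return cls(
            kind="interval",
            covariate_col=covariate_col,
            lower=lower,
            upper=upper,
            label=label or f"x{covariate_col} in [{lower}, {upper}]",
        )

    @classmethod
    def at_value(
        cls,
        values,
        P: int,
        treatment_col: int = 1,
        interactions: bool = True,
        label: str = "",
    ) -> "PopulationSpec":
        """Design rows for a covariate profile under the canonical layout
        ``(1, T, covariates..., covariates*T...)`` (or without the trailing
        interaction block when ``interactions=False``)."""
        values = np.atleast_1d(np.asarray(values, dtype=np.float64))
        expected = 2 + (2 if interactions else 1) * values.size
        if P != expected:
            raise ValueError(
                f"design has P={P} columns; a profile of {values.size} covariates "
                f"with interactions={interactions} implies P={expected}"
            )
        rows = {}
        for T in (0.0, 1.0):
            row = [1.0, T, *values]
            if interactions:
                row += list(values * T)
            rows[T] = np.asarray(row)
        if treatment_col != 1:
            raise ValueError("canonical value rows assume treatment_col == 1")
        return cls(
            kind="value",
            x_control=rows[0.0],
            x_treated=rows[1.0],
            label=label or f"x={values.tolist()}",
        )


@dataclass
class EffectDraws:
    """Per-draw pooled treatment differences on the probability scale."""

    delta: np.ndarray  # (L, K)
    delta_w: np.ndarray  # (L,)
    theta_treated: np.ndarray  # (L, K)
    theta_control: np.ndarray  # (L, K)
    weights: np.ndarray
    population: PopulationSpec
    outcome_names: list[str] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.delta.shape[0]

    @property
    def K(self) -> int:
        return self.delta.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        names = self.outcome_names or [f"y{k + 1}" for k in range(self.K)]
        df = pd.DataFrame(self.delta, columns=[f"delta_{n}" for n in names])
        df.insert(0, "draw", np.arange(self.L))
        df["delta_w"] = self.delta_w
        return df

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
        names = self.outcome_names or [f"y{k + 1}" for k in range(self.K)]
        cols = {f"delta_{n}": self.delta[:, k] for k, n in enumerate(names)}
        cols["delta_w"] = self.delta_w
        rows = []
        for name, v in cols.items():
            rows.append(
                {
                    "parameter": name,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1),
                    f"q{lo:.3f}": np.quantile(v, lo),
                    f"q{hi:.3f}": np.quantile(v, hi),
                }
            )
        return pd.DataFrame(rows)


def _normalize_weights(w, K: int) -> np.ndarray:
    w = np.atleast_1d(np.asarray(w, dtype=np.float64))
    if w.shape != (K,):
        raise ValueError(f"weights must have length K={K}")
    if np.any(w < 0):
        raise ValueError("negative importance weight")
    s = w.sum()
    if s <= 0:
        raise ValueError("weights must not all be zero")
    return w / s


def linear_predictor(x_row: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Linear predictors ``psi_q = x' gamma_q`` for one coefficient matrix.

    ``coefs`` has shape (Q-1, P) — one row of regression coefficients per
    free category (use :meth:`PosteriorDraws`-derived matrices; the
    reference category is implicit).
    """
    x_row = np.asarray(x_row, dtype=np.float64)
    coefs = np.asarray(coefs, dtype=np.float64)
    if x_row.shape[-1] != coefs.shape[-1]:
        raise ValueError("covariate vector length does not match coefficients")
    return x_row @ coefs.T


def cluster_effects(
    phi_treated: np.ndarray, phi_control: np.ndarray, space: JointResponseSpace
) -> np.ndarray:
    """Per-cluster success-probability differences ``theta_A - theta_C``."""
    return phi_to_theta(phi_treated, space) - phi_to_theta(phi_control, space)


def pool_clusters(delta_j: np.ndarray, n_j: np.ndarray) -> np.ndarray:
    """Cluster-size-weighted average ``sum_j n_j delta_j / sum_j n_j``."""
    delta_j = np.atleast_2d(np.asarray(delta_j, dtype=np.float64))
    n_j = np.asarray(n_j, dtype=np.float64)
    if len(n_j) != delta_j.shape[0] or len(n_j) == 0:
        raise ValueError("need one positive size per cluster estimate")
    if np.any(n_j <= 0):
        raise ValueError("cluster sizes must be positive")
    return (n_j[:, None] * delta_j).sum(axis=0) / n_j.sum()


def compensatory(delta: np.ndarray, w) -> np.ndarray:
    """Weighted composite difference ``delta(w) = sum_k w_k delta_k``."""
    delta = np.asarray(delta, dtype=np.float64)
    w = _normalize_weights(w, delta.shape[-1])
    return delta @ w


def _coef_matrices(
    draws: PosteriorDraws, l: int, P: int, cluster_mode: str = "observed"
) -> np.ndarray:
    """Full (J, Q-1, P) coefficient array for thinned pooled draw ``l``.

    ``cluster_mode="observed"`` uses each cluster's own coefficient draws
    (inference about the observed clusters); ``"population"``
    substitutes the random-effect mean draws for every cluster, so the
    pooled effect carries between-cluster uncertainty and refers to the
    cluster population (also how a new, unobserved cluster is predicted).
    """
    Qm = draws.space.Q - 1
    if draws.spec.model == "BMLR":
        out = np.zeros((1, Qm, P))
        out[0][:, list(draws.fixed_idx)] = draws.pooled("beta")[l]
        return out
    J = draws.gamma_j.shape[3]
    out = np.zeros((J, Qm, P))
    if cluster_mode == "population":
        out[:, :, list(draws.random_idx)] = draws.pooled("gamma_mean")[l][None]
    else:
        gj = draws.pooled("gamma_j")[l]  # (Qm, J, Pr)
        out[:, :, list(draws.random_idx)] = np.swapaxes(gj, 0, 1)
    if draws.fixed_idx:
        out[:, :, list(draws.fixed_idx)] = draws.pooled("beta")[l][None]
    return out


def subject_joint_probs(
    coefs_j: np.ndarray,
    x: np.ndarray,
    cluster: np.ndarray,
) -> np.ndarray:
    """Joint probabilities for each subject under their own design row.

    ``coefs_j`` is the (J, Q-1, P) coefficient array of one posterior draw;
    subjects are evaluated with their cluster's coefficients.
    """
    psi = np.einsum("np,nqp->nq", x, coefs_j[cluster])
    return softmax_link(psi)


def _population_mask(data: TrialDataset, population: PopulationSpec) -> np.ndarray:
    if population.kind == "full":
        return np.ones(data.n, dtype=bool)
    xcov = data.x[:, population.covariate_col]
    mask = (xcov >= population.lower) & (xcov <= population.upper)
    if not mask.any():
        raise ValueError(f"no subjects in population {population.label!r}")
    return mask


def transform_chain(
    draws: PosteriorDraws,
    data: TrialDataset,
    population: PopulationSpec,
    w,
    thin: int = 1,
    cluster_mode: str = "observed",
    counterfactual: bool = False,
    arm_design: Callable[[np.ndarray, int], np.ndarray] | None = None,
) -> EffectDraws:
    """Turn posterior coefficient draws into pooled effect draws.

    ``thin`` keeps every thin-th retained draw per chain before pooling
    chains.  ``cluster_mode`` selects the estimand: ``"observed"`` pools the
    observed clusters' own coefficient draws; ``"population"`` evaluates at
    the random-effect mean draws, so the effect refers to the population of
    clusters (between-cluster uncertainty included).  ``counterfactual=True``
    averages every population subject under both arms and requires
    ``arm_design(x_rows, T)`` to rebuild design rows (treatment and
    interaction columns) for a forced arm.
    """
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if cluster_mode not in ("observed", "population"):
        raise ValueError("cluster_mode must be 'observed' or 'population'")
    if counterfactual and population.kind != "value" and arm_design is None:
        raise ValueError("counterfactual averaging needs an arm_design builder")
    space = draws.space
    K, P = space.K, data.P
    w = _normalize_weights(w, K)
    keep = np.arange(0, draws.L, thin)
    n_thin = len(keep)

    # thinned, chain-pooled index into the pooled() arrays
    pooled_idx = np.concatenate(
        [keep + c * draws.L for c in range(draws.chains)]
    )
    L_eff = len(pooled_idx)

    single_level = draws.spec.model == "BMLR"
    cl = np.zeros(data.n, dtype=np.int64) if single_level else data.cluster
    J = 1 if single_level else data.J
    arm = data.treatment

    if population.kind == "value":
        x_rows = {0: population.x_control, 1: population.x_treated}
        weights_j = (
            np.ones(1) if single_level else data.n_j.astype(np.float64)
        )
        delta = np.empty((L_eff, K))
        thA = np.empty((L_eff, K))
        thC = np.empty((L_eff, K))
        for out_i, l in enumerate(pooled_idx):
            coefs_j = _coef_matrices(draws, l, P, cluster_mode)
            psiC = np.einsum("p,jqp->jq", x_rows[0], coefs_j)
            psiA = np.einsum("p,jqp->jq", x_rows[1], coefs_j)
            dj = cluster_effects(softmax_link(psiA), softmax_link(psiC), space)
            delta[out_i] = pool_clusters(dj, weights_j)
            thA[out_i] = pool_clusters(phi_to_theta(softmax_link(psiA), space), weights_j)
            thC[out_i] = pool_clusters(phi_to_theta(softmax_link(psiC), space), weights_j)
        return EffectDraws(
            delta=delta,
            delta_w=compensatory(delta, w),
            theta_treated=thA,
            theta_control=thC,
            weights=w,
            population=population,
            outcome_names=list(data.outcome_names),
        )

    mask = _population_mask(data, population)
    if counterfactual:
        xs = data.x[mask]
        cls = cl[mask]
        x_by_arm = {t: np.asarray(arm_design(xs, t), dtype=np.float64) for t in (0, 1)}
        cell = {t: cls for t in (0, 1)}
    else:
        x_by_arm, cell = {}, {}
        for t in (0, 1):
            sel = mask & (arm == t)
            x_by_arm[t] = data.x[sel]
            cell[t] = cl[sel]
    counts = {t: np.bincount(cell[t], minlength=J) for t in (0, 1)}
    ok = (counts[0] > 0) & (counts[1] > 0)
    if not ok.any():
        raise ValueError(
            f"population {population.label!r} has no cluster with both arms observed"
        )
    weights_j = (counts[0] + counts[1])[ok].astype(np.float64)
    # one-hot cluster indicators for fast cell averaging
    onehot = {
        t: (np.equal.outer(np.arange(J), cell[t]).astype(np.float64) / np.maximum(counts[t], 1)[:, None])
        for t in (0, 1)
    }

    delta = np.empty((L_eff, K))
    thA = np.empty((L_eff, K))
    thC = np.empty((L_eff, K))
    for out_i, l in enumerate(pooled_idx):
        coefs_j = _coef_matrices(draws, l, P, cluster_mode)
        phi_bar = {}
        for t in (0, 1):
            phi = subject_joint_probs(coefs_j, x_by_arm[t], cell[t])
            phi_bar[t] = onehot[t] @ phi  # (J, Q) cell means
        dj = cluster_effects(phi_bar[1][ok], phi_bar[0][ok], space)
        delta[out_i] = pool_clusters(dj, weights_j)
        thA[out_i] = pool_clusters(phi_to_theta(phi_bar[1][ok], space), weights_j)
        thC[out_i] = pool_clusters(phi_to_theta(phi_bar[0][ok], space), weights_j)

    return EffectDraws(
        delta=delta,
        delta_w=compensatory(delta, w),
        theta_treated=thA,
        theta_control=thC,
        weights=w,
        population=population,
        outcome_names=list(data.outcome_names),
    )


def transform_bmb(
    bmb: BmbDraws,
    w,
    population: PopulationSpec | None = None,
    outcome_names: list[str] | None = None,
) -> EffectDraws:
    """Effect draws from the Dirichlet posterior: per-arm phi differences.

    No covariates or clusters are involved (pooling over the single
    pseudo-cluster is the identity); subpopulations are handled upstream by
    fitting on the subset of the data.
    """
    space = bmb.space
    w = _normalize_weights(w, space.K)
    thA = phi_to_theta(bmb.phi[1], space)
    thC = phi_to_theta(bmb.phi[0], space)
    delta = thA - thC
    return EffectDraws(
        delta=delta,
        delta_w=compensatory(delta, w),
        theta_treated=thA,
        theta_control=thC,
        weights=w,
        population=population or PopulationSpec.full(),
        outcome_names=list(outcome_names or []),
    )
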