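"""Synthetic trial generator and the operating-characteristics study.

The generating model is a two-level mixed-effects multinomial logistic
regression for K=2 correlated binary outcomes: per cluster j and subject i,

    psi_q = (g0_q + u0_jq) + (g1_q + u1_jq) T + b2_q w + b3_q w T,
    (u0_jq, u1_jq) ~ N(0, Sigma_q),   w ~ N(0, 1),

with joint category drawn from softmax(psi) over the four outcome patterns.
The default coefficients (``TRUE_COEFFICIENTS``) encode a heterogeneous
treatment effect: the pooled average treatment difference is exactly zero
(the least favorable null for the Any and Compensatory rules), while the
subpopulation with the covariate between one SD below the mean and the mean
has a positive conditional effect delta ~ (0.116, 0.069), delta(w) ~ 0.092,
with negatively correlated outcomes.  ``Sigma_q = 0.1 I`` for every free
category.

``run_study`` replays the full pipeline (generate -> fit -> transform ->
decide) over replicate datasets and tabulates superiority proportions with
binomial standard errors, plus coefficient-bias summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .joint_response import build_joint_response_space, phi_to_theta, softmax_link
from .data import TrialDataset
from .model import ModelSpec, PriorSpec, fit_bmb, fit_bmlr, fit_bmmlr
from .effects import PopulationSpec, compensatory, transform_bmb, transform_chain
from .decisions import DecisionRule, decide

__all__ = [
    "TRUE_COEFFICIENTS",
    "SIGMA_TRUE",
    "Scenario",
    "McmcSettings",
    "OperatingCharacteristics",
    "default_scenario",
    "generate_dataset",
    "true_effects_oracle",
    "run_study",
]

#: True regression coefficients of the study's generating model, one row per
#: free joint category (the all-zero reference row is implicit); columns are
#: (intercept, T, w, w*T).
TRUE_COEFFICIENTS = np.array(
    [
        [0.000, 0.000, 1.027, -2.055],
        [0.433, 0.000, 0.601, -1.201],
        [0.433, 0.000, 0.427, -0.854],
    ]
)

#: Random-effect covariance (intercept, treatment slope) per free category.
SIGMA_TRUE = 0.1 * np.eye(2)

#: Conditional-effect condition for the regression models: the covariate
#: value one SD below the mean (true effect delta = (0.25, 0.15)).
CATE_VALUE = -1.0

#: Conditional-effect band for the subsampling (BMB) analysis: between one
#: SD below the mean and the mean (true effect delta = (0.116, 0.069)).
CATE_INTERVAL = (-1.0, 0.0)


@dataclass(frozen=True)
class Scenario:
    """A data-generating configuration for the simulation study."""

    coefficients: np.ndarray = field(default_factory=lambda: TRUE_COEFFICIENTS.copy())
    sigma: np.ndarray = field(default_factory=lambda: SIGMA_TRUE.copy())
    J: int = 10
    n_j: int = 10  # subjects per arm per cluster
    K: int = 2
    random_idx: tuple[int, ...] = (0, 1)
    fixed_idx: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        Qm = 2**self.K - 1
        coef = np.asarray(self.coefficients, dtype=np.float64)
        if coef.shape[0] != Qm:
            raise ValueError(f"coefficients must have {Qm} rows (reference implicit)")
        if self.J < 1 or self.n_j < 1:
            raise ValueError("J and n_j must be positive")
        eigs = np.linalg.eigvalsh(np.asarray(self.sigma, dtype=np.float64))
        if np.any(eigs < -1e-12):
            raise ValueError("sigma must be positive semi-definite")

    @property
    def P(self) -> int:
        return self.coefficients.shape[1]

    def model_spec(self, model: str) -> ModelSpec:
        if model == "BMMLR":
            return ModelSpec("BMMLR", self.K, self.random_idx, self.fixed_idx)
        if model == "BMLR":
            return ModelSpec("BMLR", self.K, (), tuple(range(self.P)))
        return ModelSpec("BMB", self.K)


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings; full-mode defaults follow the study protocol."""

    L: int = 50_000
    burnin: int = 10_000
    chains: int = 2
    thin: int = 10

    @classmethod
    def scaled(cls) -> "McmcSettings":
        """Desk-scale settings: one chain of 2000 retained + 500 burn-in,
        thinned by 5 in the transformation (~400 effect draws, enough
        resolution for a 0.975 cutoff)."""
        return cls(L=2000, burnin=500, chains=1, thin=5)


def default_scenario(J: int = 10, n_j: int = 10) -> Scenario:
    """The study's scenario at a given number of clusters / cluster size."""
    return Scenario(J=J, n_j=n_j)


def generate_dataset(scenario: Scenario, seed) -> TrialDataset:
    """Draw one trial dataset from the mixed-effects generating model.

    Each cluster receives ``n_j`` subjects in EACH arm; the covariate is
    standard normal per subject; random intercept and treatment slope are
    drawn per category independently with common covariance ``sigma``.
    """
    rng = np.random.default_rng(seed)
    space = build_joint_response_space(scenario.K)
    Qm = space.Q - 1
    J, n_j = scenario.J, scenario.n_j
    n = 2 * J * n_j
    cluster = np.repeat(np.arange(J), 2 * n_j)
    T = np.tile(np.repeat([0.0, 1.0], n_j), J)
    w = rng.standard_normal(n)
    x = np.column_stack([np.ones(n), T, w, w * T])

    chol = np.linalg.cholesky(scenario.sigma + 1e-15 * np.eye(2))
    u = rng.standard_normal((J, Qm, 2)) @ chol.T  # (J, Qm, [u0, u1])

    coef = scenario.coefficients  # (Qm, 4)
    psi = (
        coef[:, 0] + u[cluster, :, 0]
        + (coef[:, 1] + u[cluster, :, 1]) * T[:, None]
        + np.outer(w, coef[:, 2])
        + np.outer(w * T, coef[:, 3])
    )
    phi = softmax_link(psi)
    cdf = np.cumsum(phi, axis=1)
    cat = (rng.random(n)[:, None] > cdf[:, :-1]).sum(axis=1)
    y = space.H[cat]
    return TrialDataset(
        y=y,
        x=x,
        cluster=cluster,
        treatment_col=1,
        outcome_names=["y1", "y2"],
        covariate_names=["const", "treatment", "w", "w_x_treatment"],
    )


def true_effects_oracle(
    scenario: Scenario,
    population: PopulationSpec,
    mc_size: int = 1_000_000,
    seed=None,
    weights=(0.5, 0.5),
    include_random_effects: bool = True,
):
    """Brute-force Monte-Carlo truth for delta, delta(w) and the outcome
    correlation under a scenario.

    Samples covariates from the population definition (truncated normal for
    intervals), random effects from N(0, sigma) per category, averages the
    arm-wise joint probabilities, converts to success probabilities and
    differences.  Returns a dict with ``delta``, ``delta_w``, ``rho``,
    ``theta_treated``, ``theta_control``.
    """
    rng = np.random.default_rng(seed)
    space = build_joint_response_space(scenario.K)
    Qm = space.Q - 1
    if population.kind == "full":
        w_cov = rng.standard_normal(mc_size)
    elif population.kind == "interval":
        w_cov = stats.truncnorm.rvs(
            population.lower, population.upper, size=mc_size, random_state=rng
        )
    else:  # value: both design rows share the covariate entry
        w_cov = np.full(mc_size, population.x_control[2])
    if include_random_effects:
        chol = np.linalg.cholesky(scenario.sigma + 1e-15 * np.eye(2))
        u = rng.standard_normal((mc_size, Qm, 2)) @ chol.T
    else:
        u = np.zeros((mc_size, Qm, 2))

    coef = scenario.coefficients
    phi_bar = {}
    for t in (0.0, 1.0):
        psi = (
            coef[:, 0] + u[:, :, 0]
            + (coef[:, 1] + u[:, :, 1]) * t
            + np.outer(w_cov, coef[:, 2])
            + np.outer(w_cov * t, coef[:, 3])
        )
        phi_bar[t] = softmax_link(psi).mean(axis=0)
    theta_a = phi_to_theta(phi_bar[1.0], space)
    theta_c = phi_to_theta(phi_bar[0.0], space)
    delta = theta_a - theta_c
    phi_pop = 0.5 * (phi_bar[0.0] + phi_bar[1.0])
    th = phi_to_theta(phi_pop, space)
    p11 = phi_pop @ (space.H[:, 0] * space.H[:, 1])
    rho = (p11 - th[0] * th[1]) / np.sqrt(
        th[0] * (1 - th[0]) * th[1] * (1 - th[1])
    )
    return {
        "delta": delta,
        "delta_w": float(compensatory(delta, np.asarray(weights))),
        "rho": float(rho),
        "theta_treated": theta_a,
        "theta_control": theta_c,
    }


@dataclass
class OperatingCharacteristics:
    """Superiority proportions (with binomial SEs) and bias summaries."""

    table: pd.DataFrame  # model x rule x population -> p, se
    bias: pd.DataFrame
    scenario: Scenario
    reps: int
    failures: list = field(default_factory=list)


def _default_rules() -> dict[str, DecisionRule]:
    return {
        "Any": DecisionRule("Any", alpha=0.05, sided=1),
        "All": DecisionRule("All", alpha=0.05, sided=1),
        "Compensatory": DecisionRule("Compensatory", weights=(0.5, 0.5), alpha=0.05, sided=1),
    }


def _default_populations(P: int = 4) -> dict[str, PopulationSpec]:
    return {
        "ATE": PopulationSpec.full("ATE"),
        "CATE": PopulationSpec.at_value([CATE_VALUE], P, label="CATE"),
    }


def _default_bmb_populations() -> dict[str, PopulationSpec]:
    # the counts-only model cannot condition on a covariate value; its
    # conditional analysis subsamples the adjacent covariate band instead
    return {
        "ATE": PopulationSpec.full("ATE"),
        "CATE": PopulationSpec.interval(2, *CATE_INTERVAL, label="CATE"),
    }


def run_study(
    scenario: Scenario,
    models=("BMMLR", "BMLR", "BMB"),
    rules: dict[str, DecisionRule] | None = None,
    populations: dict[str, PopulationSpec] | None = None,
    reps: int = 1000,
    mcmc: McmcSettings | None = None,
    prior: PriorSpec | None = None,
    seed=0,
    weights=(0.5, 0.5),
    bmb_populations: dict[str, PopulationSpec] | None = None,
    cluster_mode: str = "population",
) -> OperatingCharacteristics:
    """Replicate the generate -> fit -> transform -> decide pipeline.

    For every replicate and model, effects are transformed for each
    population and each rule is applied; superiority indicators are
    tabulated into proportions with ``se = sqrt(p(1-p)/reps)``.  BMMLR
    coefficient posterior means are accumulated into the bias report.
    Replicates whose sampler fails are recorded in ``failures`` and excluded
    from denominators, never silently dropped.

    The study targets generating-population effects, so the multilevel
    transformation defaults to ``cluster_mode="population"`` (between-cluster
    uncertainty enters the pooled effect).  ``bmb_populations`` lets the
    subsampling model's (sub)populations differ from the regression models'
    (it cannot condition on a covariate value); by default it subsamples the
    covariate band one SD below the mean when the regression models use the
    point value.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rules = rules or _default_rules()
    populations = populations or _default_populations(scenario.P)
    if bmb_populations is None:
        if any(p.kind == "value" for p in populations.values()):
            bmb_populations = _default_bmb_populations()
        else:
            bmb_populations = populations
    mcmc = mcmc or McmcSettings.scaled()
    prior = prior or PriorSpec()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(reps)

    sup: dict[tuple, list] = {}
    coef_means = []
    failures = []

    for rep, rep_ss in enumerate(rep_seeds):
        s_data, s_fit, s_bmb = rep_ss.spawn(3)
        data = generate_dataset(scenario, s_data)
        try:
            effects = _replicate_effects(
                data,
                scenario,
                models,
                populations,
                bmb_populations,
                mcmc,
                prior,
                s_fit,
                s_bmb,
                weights,
                cluster_mode,
            )
        except (np.linalg.LinAlgError, ValueError) as err:
            failures.append({"rep": rep, "error": str(err)})
            continue
        if "coef_mean" in effects:
            coef_means.append(effects.pop("coef_mean"))
        for (m, p), eff in effects.items():
            for rname, rule in rules.items():
                sup.setdefault((m, rname, p), []).append(decide(eff, rule).superior)

    rows = []
    for (m, rname, pname), inds in sup.items():
        if not inds:
            continue
        nrep = len(inds)
        p = float(np.mean(inds))
        rows.append(
            {
                "model": m,
                "rule": rname,
                "population": pname,
                "p": p,
                "se": float(np.sqrt(p * (1 - p) / nrep)),
                "reps": nrep,
            }
        )
    table = pd.DataFrame(rows)

    bias = pd.DataFrame()
    if coef_means:
        est = np.mean(coef_means, axis=0)  # (Qm, P)
        truth = scenario.coefficients
        Qm, P = truth.shape
        bias = pd.DataFrame(
            {
                "category": np.repeat(np.arange(1, Qm + 1), P),
                "coefficient": np.tile(np.arange(P), Qm),
                "truth": truth.ravel(),
                "mean_estimate": est.ravel(),
                "bias": (est - truth).ravel(),
            }
        )
    return OperatingCharacteristics(
        table=table, bias=bias, scenario=scenario, reps=reps, failures=failures
    )


def _replicate_effects(
    data,
    scenario,
    models,
    populations,
    bmb_populations,
    mcmc,
    prior,
    s_fit,
    s_bmb,
    weights,
    cluster_mode,
):
    """Fit each requested model once and transform for each population."""
    out = {}
    spawn = {m: s for m, s in zip(models, s_fit.spawn(len(models)))}
    for m in models:
        if m == "BMMLR":
            draws = fit_bmmlr(
                data,
                scenario.model_spec("BMMLR"),
                prior,
                L=mcmc.L,
                burnin=mcmc.burnin,
                chains=mcmc.chains,
                seed=None,
                chain_seeds=[s.spawn(1)[0] for s in spawn[m].spawn(mcmc.chains)],
            )
            # posterior-mean coefficient matrix for the bias report
            est = np.zeros_like(scenario.coefficients)
            est[:, list(scenario.random_idx)] = draws.pooled("gamma_mean").mean(axis=0)
            est[:, list(scenario.fixed_idx)] = draws.pooled("beta").mean(axis=0)
            out["coef_mean"] = est
            for pname, pop in populations.items():
                out[(m, pname)] = transform_chain(
                    draws, data, pop, weights, thin=mcmc.thin,
                    cluster_mode=cluster_mode,
                )
        elif m == "BMLR":
            draws = fit_bmlr(
                data,
                scenario.model_spec("BMLR"),
                prior,
                L=mcmc.L,
                burnin=mcmc.burnin,
                chains=mcmc.chains,
                seed=None,
                chain_seeds=[s.spawn(1)[0] for s in spawn[m].spawn(mcmc.chains)],
            )
            for pname, pop in populations.items():
                out[(m, pname)] = transform_chain(
                    draws, data, pop, weights, thin=mcmc.thin
                )
        elif m == "BMB":
            sub_seeds = s_bmb.spawn(len(bmb_populations))
            for (pname, pop), s in zip(bmb_populations.items(), sub_seeds):
                if pop.kind == "interval":
                    xcov = data.x[:, pop.covariate_col]
                    sub = data.subset((xcov >= pop.lower) & (xcov <= pop.upper))
                elif pop.kind == "full":
                    sub = data
                else:
                    raise ValueError("BMB supports full/interval populations only")
                bmb = fit_bmb(sub, prior.dirichlet_alpha, L=mcmc.L, seed=s)
                out[(m, pname)] = transform_bmb(
                    bmb, weights, pop, outcome_names=list(data.outcome_names)
                )
        else:
            raise ValueError(f"unknown model '{m}'")
    return out
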