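"""Posterior samplers for the three treatment-comparison models.

* ``fit_bmmlr`` — multilevel mixed-effects multinomial logistic regression.
  Cluster-varying coefficients follow a normal population distribution with
  mean ``gamma_0`` and covariance ``Sigma`` per non-reference category.
* ``fit_bmlr`` — single-level multinomial logistic regression (fixed effects
  only), the same augmentation scheme without the hierarchy.
* ``fit_bmb`` — conjugate Dirichlet-multinomial analysis of the joint
  response counts per arm, ignoring clustering and covariates.

The logistic samplers use Pólya-Gamma data augmentation with a per-category
binary-logistic reduction (Holmes-Held style): conditional on the other
categories' linear predictors, category q's multinomial contribution is a
binary logit in ``eta = psi_q - C`` with offset
``C = log(sum_{r != q} exp(psi_r) + 1)``.  Drawing ``omega ~ PG(1, eta)``
makes every coefficient block conditionally Gaussian and the random-effect
covariance conditionally inverse-Wishart, so a full sweep is direct sampling
throughout.  Within a sweep, each category is updated in the order
``omega -> beta -> gamma_j -> gamma_0 -> Sigma``; the order does not affect
the stationary distribution.

Identifiability: the reference category's coefficients are fixed at zero and
never stored.  Chains are stored unthinned; thinning belongs to the
transformation step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._gibbs import chain_bmlr, chain_bmmlr
from .joint_response import JointResponseSpace, build_joint_response_space
from .data import TrialDataset

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "PosteriorDraws",
    "BmbDraws",
    "fit_bmmlr",
    "fit_bmlr",
    "fit_bmb",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which model, and which design columns vary over clusters.

    ``random_idx`` and ``fixed_idx`` partition the design columns; BMLR has
    an empty ``random_idx``; BMB ignores the design beyond the treatment.
    """

    model: str
    K: int
    random_idx: tuple[int, ...] = ()
    fixed_idx: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in ("BMMLR", "BMLR", "BMB"):
            raise ValueError(f"unknown model '{self.model}'")
        if set(self.random_idx) & set(self.fixed_idx):
            raise ValueError("random_idx and fixed_idx overlap")
        if self.model == "BMMLR" and not self.random_idx:
            raise ValueError("BMMLR requires at least one cluster-varying coefficient")
        if self.model == "BMLR" and self.random_idx:
            raise ValueError("BMLR is single-level: random_idx must be empty")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the logistic samplers and the Dirichlet analysis.

    Normal priors are independent N(coef_mean, coef_var) per coefficient
    (applied to fixed effects and to random-effect means alike, for every
    category).  ``sigma_df``/``sigma_scale`` parametrize the inverse-Wishart
    prior on each category's random-effect covariance;
    ``improper_sigma=True`` replaces it with the improper uniform prior.
    """

    coef_mean: float = 0.0
    coef_var: float = 10.0
    sigma_df: float = 2.0
    sigma_scale: float = 0.1
    improper_sigma: bool = False
    dirichlet_alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.coef_var <= 0:
            raise ValueError("coef_var must be positive")
        if self.sigma_scale <= 0:
            raise ValueError("sigma_scale must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, per chain.

    Shapes: ``beta (chains, L, Q-1, Pf)``, ``gamma_j (chains, L, Q-1, J, Pr)``,
    ``gamma_mean (chains, L, Q-1, Pr)``, ``sigma (chains, L, Q-1, Pr, Pr)``.
    BMLR stores only ``beta`` (with ``Pr = 0`` blocks empty).
    """

    spec: ModelSpec
    prior: PriorSpec
    space: JointResponseSpace
    beta: np.ndarray
    gamma_j: np.ndarray
    gamma_mean: np.ndarray
    sigma: np.ndarray
    L: int
    burnin: int
    seed: int | None
    random_idx: tuple[int, ...] = ()
    fixed_idx: tuple[int, ...] = ()

    @property
    def chains(self) -> int:
        return self.beta.shape[0]

    def pooled(self, name: str) -> np.ndarray:
        """Concatenate a parameter block across chains: (chains*L, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])


@dataclass
class BmbDraws:
    """Closed-form Dirichlet posterior draws of joint probabilities per arm."""

    space: JointResponseSpace
    phi: dict[int, np.ndarray]  # arm (0=control, 1=experimental) -> (L, Q)
    counts: dict[int, np.ndarray]
    alpha0: np.ndarray
    L: int
    seed: int | None


def _check_mcmc_args(L: int, burnin: int, chains: int) -> None:
    if L <= 0:
        raise ValueError("L must be positive")
    if burnin < 0:
        raise ValueError("burnin must be non-negative")
    if chains < 1:
        raise ValueError("chains must be >= 1")


def fit_bmmlr(
    data: TrialDataset,
    spec: ModelSpec,
    prior: PriorSpec,
    L: int,
    burnin: int,
    chains: int = 1,
    seed: int | None = None,
    chain_seeds: list | None = None,
) -> PosteriorDraws:
    """Pólya-Gamma Gibbs sampler for the multilevel mixed-effects model.

    Clusters of size 1 are handled through prior shrinkage of their random
    effect — no special-casing.  Returns unthinned post-burn-in chains.
    """
    _check_mcmc_args(L, burnin, chains)
    if spec.model != "BMMLR":
        raise ValueError("spec.model must be 'BMMLR'")
    space = build_joint_response_space(spec.K)
    Qm = space.Q - 1
    ridx = list(spec.random_idx)
    fidx = list(spec.fixed_idx)
    Pr, Pf = len(ridx), len(fidx)
    J, n = data.J, data.n
    Xr = np.ascontiguousarray(data.x[:, ridx])
    Xf = np.ascontiguousarray(data.x[:, fidx]) if Pf else np.zeros((n, 0))
    cl = data.cluster
    order = np.argsort(cl, kind="stable").astype(np.int64)
    ptr = np.zeros(J + 1, dtype=np.int64)
    ptr[1:] = np.cumsum(np.bincount(cl, minlength=J))
    cat = space.category_of(data.y).astype(np.int64)

    if prior.improper_sigma:
        nu0, S0 = -(Pr + 1.0), np.zeros((Pr, Pr))
        if J - Pr - 1 <= Pr - 1:
            raise ValueError(
                "improper uniform Sigma prior needs J > 2*Pr clusters "
                f"(J={J}, Pr={Pr})"
            )
    else:
        nu0, S0 = prior.sigma_df, prior.sigma_scale * np.eye(Pr)
    prior_prec = np.eye(Pf) / prior.coef_var if Pf else np.zeros((0, 0))
    prior_prec_r = np.eye(Pr) / prior.coef_var
    b0f = np.full(Pf, prior.coef_mean)
    b0r = np.full(Pr, prior.coef_mean)

    if chain_seeds is None:
        chain_seeds = [[0 if seed is None else seed, c] for c in range(chains)]
    if len(chain_seeds) != chains:
        raise ValueError("need one chain seed per chain")

    out_beta = np.zeros((chains, L, Qm, Pf))
    out_gj = np.zeros((chains, L, Qm, J, Pr))
    out_g0 = np.zeros((chains, L, Qm, Pr))
    out_sig = np.zeros((chains, L, Qm, Pr, Pr))

    sigma_init = np.eye(Pr) if prior.improper_sigma else prior.sigma_scale * np.eye(Pr)
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        try:
            chain_bmmlr(
                Xr,
                Xf,
                cl.astype(np.int64),
                order,
                ptr,
                cat,
                Qm,
                prior_prec,
                b0f,
                prior_prec_r,
                b0r,
                float(nu0),
                S0,
                sigma_init,
                L,
                burnin,
                rng,
                out_beta[c],
                out_gj[c],
                out_g0[c],
                out_sig[c],
            )
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"Cholesky failure in chain {c} (n={n}, J={J}): {err}"
            ) from err

    return PosteriorDraws(
        spec=spec,
        prior=prior,
        space=space,
        beta=out_beta,
        gamma_j=out_gj,
        gamma_mean=out_g0,
        sigma=out_sig,
        L=L,
        burnin=burnin,
        seed=seed,
        random_idx=tuple(ridx),
        fixed_idx=tuple(fidx),
    )


def fit_bmlr(
    data: TrialDataset,
    spec: ModelSpec,
    prior: PriorSpec,
    L: int,
    burnin: int,
    chains: int = 1,
    seed: int | None = None,
    chain_seeds: list | None = None,
) -> PosteriorDraws:
    """Single-level multinomial logistic sampler (fixed effects only)."""
    _check_mcmc_args(L, burnin, chains)
    if spec.model != "BMLR":
        raise ValueError("spec.model must be 'BMLR'")
    space = build_joint_response_space(spec.K)
    Qm = space.Q - 1
    fidx = list(spec.fixed_idx) if spec.fixed_idx else list(range(data.P))
    Pf = len(fidx)
    X = np.ascontiguousarray(data.x[:, fidx])
    cat = space.category_of(data.y).astype(np.int64)
    prior_prec = np.eye(Pf) / prior.coef_var
    b0 = np.full(Pf, prior.coef_mean)

    if chain_seeds is None:
        chain_seeds = [[0 if seed is None else seed, c] for c in range(chains)]
    if len(chain_seeds) != chains:
        raise ValueError("need one chain seed per chain")

    out_beta = np.zeros((chains, L, Qm, Pf))
    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        try:
            chain_bmlr(X, cat, Qm, prior_prec, b0, L, burnin, rng, out_beta[c])
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"Cholesky failure in chain {c} (n={data.n}): {err}"
            ) from err

    empty = np.zeros((chains, L, Qm, 0))
    return PosteriorDraws(
        spec=spec,
        prior=prior,
        space=space,
        beta=out_beta,
        gamma_j=np.zeros((chains, L, Qm, 0, 0)),
        gamma_mean=empty,
        sigma=np.zeros((chains, L, Qm, 0, 0)),
        L=L,
        burnin=burnin,
        seed=seed,
        random_idx=(),
        fixed_idx=tuple(fidx),
    )


def fit_bmb(
    data: TrialDataset,
    alpha0: np.ndarray | float = 0.01,
    L: int = 2000,
    seed: int | None = None,
) -> BmbDraws:
    """Conjugate Dirichlet-multinomial posterior draws of phi per arm.

    Counts each arm's joint response categories (rows of H) and draws L
    independent vectors from Dirichlet(counts + alpha0).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    space = build_joint_response_space(data.K)
    alpha0 = np.broadcast_to(np.asarray(alpha0, dtype=np.float64), (space.Q,)).copy()
    if np.any(alpha0 <= 0):
        raise ValueError("dirichlet hyperparameters must be positive")
    cat = space.category_of(data.y)
    arm = data.treatment
    rng = np.random.default_rng(seed)
    phi, counts = {}, {}
    for t in (0, 1):
        mask = arm == t
        if not mask.any():
            raise ValueError(f"arm {t} has no subjects")
        counts[t] = np.bincount(cat[mask], minlength=space.Q).astype(np.float64)
        phi[t] = rng.dirichlet(counts[t] + alpha0, size=L)
    return BmbDraws(space=space, phi=phi, counts=counts, alpha0=alpha0, L=L, seed=seed)
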