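"""Convergence diagnostics and chain post-processing.

The multivariate potential scale reduction factor (MPSRF) follows Brooks &
Gelman: with m chains of length L and parameter covariance split into the
within-chain average W and the between-chain covariance B/L,

    MPSRF = (L-1)/L + (m+1)/m * lambda_1,

where lambda_1 is the largest eigenvalue of W^{-1} B / L.  Values near 1
indicate no evidence of non-convergence (1.10 is the conventional
threshold).  Univariate PSRFs use the classic Gelman-Rubin form.  None of
the functions mutate their input chains.
"""

from __future__ import annotations

import numpy as np
from statsmodels.tsa.stattools import acf

__all__ = ["mpsrf", "psrf", "autocorr", "thin"]


def _as_chains(chains: np.ndarray) -> np.ndarray:
    arr = np.asarray(chains, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("chains must be (m, L) or (m, L, p)")
    return arr


def mpsrf(chains: np.ndarray) -> float:
    """Brooks-Gelman multivariate PSRF over a parameter block.

    ``chains`` has shape (m, L, p) with m >= 2 chains.  Identical chains
    give 1 (up to the (L-1)/L finite-sample factor); chains exploring
    disjoint regions blow up well past 1.1.
    """
    arr = _as_chains(chains)
    m, L, p = arr.shape
    if m < 2:
        raise ValueError("MPSRF needs at least two chains")
    if L < 10:
        raise ValueError("chains too short for a meaningful PSRF")
    means = arr.mean(axis=1)  # (m, p)
    W = np.zeros((p, p))
    for c in range(m):
        dev = arr[c] - means[c]
        W += dev.T @ dev / (L - 1)
    W /= m
    grand = means.mean(axis=0)
    dm = means - grand
    B_over_L = dm.T @ dm / (m - 1)  # = B / L
    # ridge keeps the solve defined when a parameter has (near-)zero
    # within-chain variance, e.g. two identical chains
    W_reg = W + 1e-12 * np.eye(p) * max(1.0, np.trace(W))
    lam = np.linalg.eigvals(np.linalg.solve(W_reg, B_over_L)).real.max() if p else 0.0
    return float((L - 1) / L + (m + 1) / m * lam)


def psrf(chains: np.ndarray) -> np.ndarray:
    """Classic univariate Gelman-Rubin PSRF per parameter."""
    arr = _as_chains(chains)
    m, L, p = arr.shape
    if m < 2:
        raise ValueError("PSRF needs at least two chains")
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B = L * means.var(axis=0, ddof=1)
    var_plus = (L - 1) / L * W + B / L
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    out[np.isnan(out)] = 1.0  # constant-everywhere parameter
    return out


def autocorr(chain: np.ndarray, lags) -> np.ndarray:
    """Sample autocorrelation of one chain at the requested lags.

    A constant chain has undefined autocorrelation; NaN is returned at every
    positive lag as the flagged value.
    """
    chain = np.asarray(chain, dtype=np.float64)
    if chain.ndim != 1:
        raise ValueError("autocorr expects a single 1-d chain")
    lags = np.atleast_1d(np.asarray(lags, dtype=np.int64))
    if lags.max(initial=0) >= len(chain):
        raise ValueError("lag exceeds chain length")
    if np.ptp(chain) == 0:
        return np.where(lags == 0, 1.0, np.nan)
    full = acf(chain, nlags=int(lags.max(initial=0)), fft=True)
    return full[lags]


def thin(chains: np.ndarray, factor: int) -> np.ndarray:
    """Keep every factor-th draw along the iteration axis (axis 1 for
    multi-chain arrays, axis 0 for a single chain)."""
    arr = np.asarray(chains)
    if factor < 1:
        raise ValueError("thinning factor must be >= 1")
    axis = 1 if arr.ndim >= 2 else 0
    if factor > arr.shape[axis]:
        raise ValueError("thinning factor exceeds chain length")
    slicer = [slice(None)] * arr.ndim
    slicer[axis] = slice(0, None, factor)
    return arr[tuple(slicer)]
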