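"""Compiled inner loops of the Pólya-Gamma Gibbs samplers.

Everything here is numba-jitted and operates on plain arrays; the public
fitting functions in :mod:`bmmlr.model` prepare inputs, run one kernel per
chain and package the outputs.  The per-category sweep implements the
binary-logistic reduction described in :mod:`bmmlr.model`.
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .polya_gamma import _sample_pg1


@nb.njit(cache=True)
def _draw_mvn_prec(prec, rhs, rng):
    """Draw from N(prec^{-1} rhs, prec^{-1}) via one Cholesky of prec."""
    L = np.linalg.cholesky(prec)
    d = prec.shape[0]
    y = np.empty(d)
    for i in range(d):
        s = rhs[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    m = np.empty(d)
    for i in range(d - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, d):
            s -= L[k, i] * m[k]
        m[i] = s / L[i, i]
    x = np.empty(d)
    for i in range(d - 1, -1, -1):
        s = rng.standard_normal()
        for k in range(i + 1, d):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return m + x


@nb.njit(cache=True)
def _inv_wishart(df, S, rng):
    """One inverse-Wishart(df, S) draw via the Bartlett decomposition."""
    d = S.shape[0]
    Lc = np.linalg.cholesky(np.linalg.inv(S))
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for k in range(i):
            A[i, k] = rng.standard_normal()
    LA = Lc @ A
    W = LA @ LA.T
    sig = np.linalg.inv(W)
    return 0.5 * (sig + sig.T)


@nb.njit(cache=True)
def _pg_step(psi, cat, q, omega, v, rng):
    """Offset, PG draw and working response for one category.

    C_i = log(sum_{r != q} exp(psi_ir) + 1);  eta_i = psi_iq - C_i;
    omega_i ~ PG(1, eta_i);  v_i = (I(cat_i = q) - 1/2)/omega_i + C_i.
    """
    n, Qm = psi.shape
    for i in range(n):
        m = 0.0
        for r in range(Qm):
            if r != q and psi[i, r] > m:
                m = psi[i, r]
        s = np.exp(-m)
        for r in range(Qm):
            if r != q:
                s += np.exp(psi[i, r] - m)
        C = m + np.log(s)
        eta = psi[i, q] - C
        omega[i] = _sample_pg1(eta, rng)
        kappa = 0.5 if cat[i] == q else -0.5
        v[i] = kappa / omega[i] + C


@nb.njit(cache=True)
def chain_bmmlr(
    Xr,
    Xf,
    cl,
    order,
    ptr,
    cat,
    Qm,
    prior_prec_f,
    b0f,
    prior_prec_r,
    b0r,
    nu0,
    S0,
    sigma_init,
    L,
    burnin,
    rng,
    out_beta,
    out_gj,
    out_g0,
    out_sig,
):
    """One MCMC chain of the multilevel sampler (results into out_*)."""
    n, Pr = Xr.shape
    Pf = Xf.shape[1]
    J = ptr.shape[0] - 1
    beta = np.zeros((Qm, Pf))
    gj = np.zeros((Qm, J, Pr))
    g0 = np.zeros((Qm, Pr))
    sigma = np.empty((Qm, Pr, Pr))
    for q in range(Qm):
        sigma[q] = sigma_init
    psi = np.zeros((n, Qm))
    omega = np.empty(n)
    v = np.empty(n)
    resid2 = np.empty(n)

    for it in range(burnin + L):
        for q in range(Qm):
            _pg_step(psi, cat, q, omega, v, rng)

            if Pf > 0:
                prec = prior_prec_f.copy()
                rhs = prior_prec_f @ b0f
                for i in range(n):
                    ri = v[i]
                    for a in range(Pr):
                        ri -= Xr[i, a] * gj[q, cl[i], a]
                    wi = omega[i]
                    for a in range(Pf):
                        rhs[a] += wi * Xf[i, a] * ri
                        for b in range(Pf):
                            prec[a, b] += wi * Xf[i, a] * Xf[i, b]
                beta[q] = _draw_mvn_prec(prec, rhs, rng)

            for i in range(n):
                r2 = v[i]
                for a in range(Pf):
                    r2 -= Xf[i, a] * beta[q, a]
                resid2[i] = r2

            sig_inv = np.linalg.inv(sigma[q])
            sg0 = sig_inv @ g0[q]
            for j in range(J):
                prec_j = sig_inv.copy()
                rhs_j = sg0.copy()
                for t in range(ptr[j], ptr[j + 1]):
                    i = order[t]
                    wi = omega[i]
                    for a in range(Pr):
                        rhs_j[a] += wi * Xr[i, a] * resid2[i]
                        for b in range(Pr):
                            prec_j[a, b] += wi * Xr[i, a] * Xr[i, b]
                gj[q, j] = _draw_mvn_prec(prec_j, rhs_j, rng)

            prec0 = J * sig_inv + prior_prec_r
            rhs0 = prior_prec_r @ b0r
            tmp = np.zeros(Pr)
            for j in range(J):
                for a in range(Pr):
                    tmp[a] += gj[q, j, a]
            rhs0 += sig_inv @ tmp
            g0[q] = _draw_mvn_prec(prec0, rhs0, rng)

            Sn = S0.copy()
            for j in range(J):
                for a in range(Pr):
                    for b in range(Pr):
                        Sn[a, b] += (gj[q, j, a] - g0[q, a]) * (gj[q, j, b] - g0[q, b])
            sigma[q] = _inv_wishart(nu0 + J, Sn, rng)

            for i in range(n):
                s = 0.0
                for a in range(Pr):
                    s += Xr[i, a] * gj[q, cl[i], a]
                for a in range(Pf):
                    s += Xf[i, a] * beta[q, a]
                psi[i, q] = s

        if it >= burnin:
            keep = it - burnin
            out_beta[keep] = beta
            out_gj[keep] = gj
            out_g0[keep] = g0
            out_sig[keep] = sigma


@nb.njit(cache=True)
def chain_bmlr(X, cat, Qm, prior_prec, b0, L, burnin, rng, out_beta):
    """One MCMC chain of the single-level (fixed-effects) sampler."""
    n, P = X.shape
    beta = np.zeros((Qm, P))
    psi = np.zeros((n, Qm))
    omega = np.empty(n)
    v = np.empty(n)
    for it in range(burnin + L):
        for q in range(Qm):
            _pg_step(psi, cat, q, omega, v, rng)
            prec = prior_prec.copy()
            rhs = prior_prec @ b0
            for i in range(n):
                wi = omega[i]
                for a in range(P):
                    rhs[a] += wi * X[i, a] * v[i]
                    for b in range(P):
                        prec[a, b] += wi * X[i, a] * X[i, b]
            beta[q] = _draw_mvn_prec(prec, rhs, rng)
            for i in range(n):
                s = 0.0
                for a in range(P):
                    s += X[i, a] * beta[q, a]
                psi[i, q] = s
        if it >= burnin:
            out_beta[it - burnin] = beta
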