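"""Exact Pólya-Gamma PG(1, c) sampling.

The Pólya-Gamma auxiliary-variable scheme renders logistic likelihoods
conditionally Gaussian: for a binary-logistic contribution
``exp(eta)^z / (1 + exp(eta))`` one draws ``omega ~ PG(1, eta)``, after which
``eta`` has a Gaussian pseudo-likelihood with precision ``omega`` and working
response ``(z - 1/2) / omega``.  PG(1, c) is the tilted Jacobi distribution
``J*(1, c/2) / 4`` and is sampled exactly with the alternating-series
rejection sampler of Devroye, using a piecewise proposal (truncated
inverse-Gaussian below the threshold ``t = 0.64``, exponential tail above it).

The sampler is scalar at heart and compiled with numba; the array front-end
:func:`polya_gamma` is what the Gibbs samplers call.  Useful identity for
testing: ``E[omega] = tanh(c/2) / (2c)`` (``= 1/4`` at ``c = 0``).
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

__all__ = ["polya_gamma", "pg_mean"]

_TRUNC = 0.64  # crossover point of the piecewise proposal
_SQRT2 = math.sqrt(2.0)


@nb.njit(cache=True)
def _norm_logcdf(x: float) -> float:
    # log Phi(x); erfc underflows near x = -37, switch to the tail expansion
    if x < -36.0:
        return -0.5 * x * x - 0.5 * math.log(2.0 * math.pi) - math.log(-x)
    return math.log(0.5 * math.erfc(-x / _SQRT2))


@nb.njit(cache=True)
def _mass_texpon(z: float) -> float:
    # probability that the proposal draws from the exponential tail (x > t)
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _norm_logcdf(b)
    xa = x0 + z + _norm_logcdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@nb.njit(cache=True)
def _rtigauss(z: float, rng) -> float:
    # inverse-Gaussian IG(1/z, 1) truncated to (0, _TRUNC]
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: rejection from the truncated chi proposal
        alpha = 0.0
        while rng.random() > alpha:
            e1 = rng.standard_exponential()
            e2 = rng.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = rng.standard_exponential()
                e2 = rng.standard_exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = rng.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if rng.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@nb.njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    # n-th term of Devroye's alternating series for the Jacobi density
    npl = n + 0.5
    if x <= _TRUNC:
        return (
            math.pi
            * npl
            * math.exp(1.5 * math.log(2.0 / (math.pi * x)) - 2.0 * npl * npl / x)
        )
    return math.pi * npl * math.exp(-0.5 * npl * npl * math.pi * math.pi * x)


@nb.njit(cache=True)
def _sample_pg1(c: float, rng) -> float:
    z = 0.5 * abs(c)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    while True:
        if rng.random() < _mass_texpon(z):
            x = _TRUNC + rng.standard_exponential() / fz
        else:
            x = _rtigauss(z, rng)
        # squeeze test on the partial sums of the alternating series
        s = _a_coef(0, x)
        y = rng.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@nb.njit(cache=True)
def _pg1_fill(c: np.ndarray, out: np.ndarray, rng) -> None:
    for i in range(c.shape[0]):
        out[i] = _sample_pg1(c[i], rng)


def polya_gamma(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one PG(1, c_i) variate for every element of ``c``.

    Parameters
    ----------
    c
        Tilting parameters (any shape); only ``|c|`` matters.
    rng
        numpy Generator; the call consumes its stream deterministically.
    """
    c = np.ascontiguousarray(c, dtype=np.float64)
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite tilting parameter passed to polya_gamma")
    flat = c.ravel()
    out = np.empty_like(flat)
    _pg1_fill(flat, out, rng)
    return out.reshape(c.shape)


def pg_mean(c: np.ndarray) -> np.ndarray:
    """Closed-form mean tanh(c/2)/(2c) of PG(1, c), with the 1/4 limit at 0."""
    c = np.asarray(c, dtype=np.float64)
    out = np.full(c.shape, 0.25)
    nz = np.abs(c) > 1e-12
    out[nz] = np.tanh(c[nz] / 2.0) / (2.0 * c[nz])
    return out
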