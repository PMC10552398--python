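"""Multivariate-Bernoulli / multinomial parametrization of K binary outcomes.

K correlated binary outcomes have a joint distribution over the ``Q = 2^K``
outcome patterns (joint response combinations).  The pattern matrix ``H``
enumerates them in a fixed order — first row all ones, last row all zeros
(the reference category), intermediate rows in decreasing binary order, so
for K=2 the categories read ({11},{10},{01},{00}).  The joint probabilities
``phi`` live on the Q-simplex and the marginal success probabilities
``theta`` are the linear maps ``theta_k = sum_q H[q,k] phi_q``.  The inverse
link from linear predictors to ``phi`` is the multinomial softmax with the
last category's predictor pinned at zero for identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointResponseSpace",
    "build_joint_response_space",
    "softmax_link",
    "phi_to_theta",
    "outcome_correlation",
    "PROB_TOL",
]

#: tolerance on the sum-to-one invariant of a joint probability vector
PROB_TOL = 1e-10

_MAX_K = 10


@dataclass(frozen=True)
class JointResponseSpace:
    """Enumeration of the 2^K joint response combinations.

    Attributes
    ----------
    K : int
        Number of binary outcomes.
    Q : int
        Number of joint categories, ``2**K``.
    H : ndarray of shape (Q, K)
        Binary pattern matrix; row ``q`` is the outcome pattern of joint
        category ``q``.  Row 0 is all ones, row Q-1 all zeros (reference).
    """

    K: int
    Q: int
    H: np.ndarray

    def category_of(self, y: np.ndarray) -> np.ndarray:
        """Map binary outcome rows to joint-category indices (rows of H)."""
        y = np.atleast_2d(np.asarray(y))
        if y.shape[-1] != self.K:
            raise ValueError(f"outcome rows have {y.shape[-1]} columns, expected K={self.K}")
        weights = 2 ** np.arange(self.K - 1, -1, -1)
        return (self.Q - 1) - y @ weights


def build_joint_response_space(K: int) -> JointResponseSpace:
    """Enumerate the joint response combinations for ``K`` binary outcomes."""
    if not isinstance(K, (int, np.integer)) or isinstance(K, bool):
        raise TypeError("K must be an integer")
    if K < 1 or K > _MAX_K:
        raise ValueError(f"K must be in [1, {_MAX_K}], got {K}")
    Q = 2**K
    # decreasing binary order: q-th row encodes the integer Q-1-q
    vals = np.arange(Q - 1, -1, -1, dtype=np.int64)
    H = (vals[:, None] >> np.arange(K - 1, -1, -1)) & 1
    H.flags.writeable = False
    return JointResponseSpace(K=K, Q=Q, H=H)


def softmax_link(psi: np.ndarray) -> np.ndarray:
    """Multinomial logistic link: linear predictors to joint probabilities.

    ``psi`` holds the Q-1 free linear predictors (the reference category's
    predictor is implicitly zero).  Works on the last axis, so chains of
    predictors can be transformed in one call.  Stabilized by subtracting the
    running maximum before exponentiation.
    """
    psi = np.asarray(psi, dtype=np.float64)
    if not np.all(np.isfinite(psi)):
        raise ValueError("non-finite linear predictor")
    full = np.concatenate([psi, np.zeros(psi.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def phi_to_theta(phi: np.ndarray, space: JointResponseSpace) -> np.ndarray:
    """Marginal success probabilities from joint probabilities: ``phi @ H``."""
    phi = np.asarray(phi, dtype=np.float64)
    if phi.shape[-1] != space.Q:
        raise ValueError(f"phi has {phi.shape[-1]} categories, expected Q={space.Q}")
    return phi @ space.H


def outcome_correlation(
    phi: np.ndarray, space: JointResponseSpace, k1: int, k2: int
) -> float:
    """Pearson correlation of two Bernoulli margins implied by ``phi``.

    ``(p11 - theta1*theta2) / sqrt(theta1(1-theta1) theta2(1-theta2))`` where
    ``p11`` is the joint success mass of outcomes ``k1`` and ``k2``.
    """
    phi = np.asarray(phi, dtype=np.float64)
    theta = phi_to_theta(phi, space)
    t1, t2 = theta[..., k1], theta[..., k2]
    if np.any(t1 <= 0) or np.any(t1 >= 1) or np.any(t2 <= 0) or np.any(t2 >= 1):
        raise ValueError("degenerate margin: correlation undefined")
    p11 = phi @ (space.H[:, k1] * space.H[:, k2])
    return (p11 - t1 * t2) / np.sqrt(t1 * (1 - t1) * t2 * (1 - t2))
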