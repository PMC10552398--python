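"""Superiority / inferiority decisions from posterior effect draws.

Four rules define the superiority region S_R on the K-variate treatment
difference delta (strict inequalities with zero throughout):

* Single       — delta_k > 0 on the designated primary outcome;
* All          — min_k delta_k > 0;
* Any          — max_k delta_k > 0, evaluated per outcome with a K-fold
                 corrected cutoff (so conclusions are reported per outcome
                 and may simultaneously flag superiority and inferiority on
                 different outcomes);
* Compensatory — delta(w) = sum_k w_k delta_k > 0.

Superiority is concluded when the posterior probability (the fraction of
draws in S_R) exceeds the cutoff p_cut, inferiority when it falls below
1 - p_cut.  Cutoffs calibrate the frequentist Type I error to alpha:
one-sided p_cut = 1 - alpha (All, Compensatory, Single) or 1 - alpha/K
(Any); two-sided variants halve alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .effects import EffectDraws, compensatory

__all__ = ["DecisionRule", "DecisionResult", "region_membership", "decide"]

_RULES = ("Single", "All", "Any", "Compensatory")


@dataclass(frozen=True)
class DecisionRule:
    """A decision rule with its calibrated posterior-probability cutoff."""

    rule: str
    weights: tuple | None = None  # Compensatory only
    alpha: float = 0.05
    sided: int = 1
    primary: int = 0  # Single rule: index of the primary outcome

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sided not in (1, 2):
            raise ValueError("sided must be 1 or 2")
        if self.rule == "Compensatory" and self.weights is None:
            raise ValueError("Compensatory rule needs importance weights")

    def p_cut(self, K: int) -> float:
        """Cutoff calibrated for K outcomes.

        One-sided: 1 - alpha/K (Any) else 1 - alpha.
        Two-sided: 1 - alpha/(2K) (Any) else 1 - alpha/2.
        """
        a = self.alpha / self.sided
        if self.rule == "Any":
            a /= K
        return 1.0 - a


@dataclass
class DecisionResult:
    """Posterior evidence and the conclusion it supports."""

    rule: DecisionRule
    p_cut: float
    posterior_prob: float | np.ndarray  # per-outcome array for the Any rule
    conclusion: str  # superior | inferior | superior & inferior | inconclusive
    superior: bool
    inferior: bool
    per_outcome: dict = field(default_factory=dict)


def region_membership(
    delta: np.ndarray, delta_w: np.ndarray | None, rule: DecisionRule
) -> np.ndarray:
    """Indicator of draws inside the superiority region S_R.

    For the Any rule returns per-outcome indicators (L, K); the region
    membership max_k delta_k > 0 is their row-wise OR.
    """
    delta = np.atleast_2d(np.asarray(delta, dtype=np.float64))
    if not np.all(np.isfinite(delta)):
        raise ValueError("non-finite effect draw")
    if rule.rule == "Single":
        return delta[:, rule.primary] > 0
    if rule.rule == "All":
        return delta.min(axis=1) > 0
    if rule.rule == "Any":
        return delta > 0
    if delta_w is None:
        delta_w = compensatory(delta, np.asarray(rule.weights))
    return np.asarray(delta_w) > 0


def decide(effects: EffectDraws, rule: DecisionRule) -> DecisionResult:
    """Apply a decision rule to posterior effect draws."""
    if effects.L == 0:
        raise ValueError("no effect draws to decide on")
    K = effects.K
    p_cut = rule.p_cut(K)
    delta_w = effects.delta_w if rule.rule == "Compensatory" and rule.weights is None else None
    if rule.rule == "Compensatory" and rule.weights is not None:
        delta_w = compensatory(effects.delta, np.asarray(rule.weights))
    member = region_membership(effects.delta, delta_w, rule)

    if rule.rule == "Any":
        p_k = member.mean(axis=0)  # per-outcome right-tail probabilities
        sup_k = p_k > p_cut
        inf_k = p_k < 1.0 - p_cut if rule.sided == 2 else np.zeros(K, dtype=bool)
        if rule.sided == 1:
            # one-sided left conclusion: every outcome must point down
            inf_k = p_k < 1.0 - p_cut
            inferior = bool(inf_k.all())
        else:
            inferior = bool(inf_k.any())
        superior = bool(sup_k.any())
        conclusion = _label(superior, inferior)
        return DecisionResult(
            rule=rule,
            p_cut=p_cut,
            posterior_prob=p_k,
            conclusion=conclusion,
            superior=superior,
            inferior=inferior,
            per_outcome={"superior": sup_k, "inferior": inf_k, "prob": p_k},
        )

    p = float(member.mean())
    superior = p > p_cut
    inferior = p < 1.0 - p_cut
    return DecisionResult(
        rule=rule,
        p_cut=p_cut,
        posterior_prob=p,
        conclusion=_label(superior, inferior),
        superior=superior,
        inferior=inferior,
    )


def _label(superior: bool, inferior: bool) -> str:
    if superior and inferior:
        return "superior & inferior"
    if superior:
        return "superior"
    if inferior:
        return "inferior"
    return "inconclusive"
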