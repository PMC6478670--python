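"""Pre-/post-test probability arithmetic for sequential detection.

A detection strategy is a chain of "tests" (recruitment filters, screening
questionnaires, clinical interviews), each of which multiplies the current
odds of the outcome by a likelihood ratio:

    posttest odds = pretest odds × LR,   odds = p / (1 − p).

The reference scenario: a general-population 3-year psychosis risk of 0.43%
rises to 15% in help-seeking samples referred for a high-risk assessment
(≈35-fold enrichment); a positive assessment raises it further to 26%
(LR ≈ 2.0, a 1.7-fold increase), a negative one lowers it to 1.56%
(LR ≈ 0.09, a ~10-fold decrease).

Fold changes are reported on the probability scale (simple risk ratios),
matching how such enrichment figures are usually quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import DomainError

__all__ = [
    "RiskEstimate",
    "update_risk",
    "derive_lr",
    "fold_change",
    "chain_tests",
    "apply_relative_risk",
]


def _check_prob(p: float, name: str) -> None:
    if not 0.0 < p < 1.0:
        raise DomainError(f"{name} must be strictly within (0, 1), got {p}")


@dataclass(frozen=True)
class RiskEstimate:
    """A pre-test probability, the likelihood ratio applied, and the result.

    Invariant: posttest odds equal pretest odds times the likelihood ratio.
    ``horizon`` is a free-text time horizon tag (e.g. "3-year").
    """

    pretest_prob: float
    likelihood_ratio: float
    posttest_prob: float
    horizon: str = ""

    @property
    def fold_change(self) -> float:
        """Post- over pre-test probability ratio."""
        return self.posttest_prob / self.pretest_prob

    def to_dict(self) -> dict:
        return {
            "pretest_prob": self.pretest_prob,
            "likelihood_ratio": self.likelihood_ratio,
            "posttest_prob": self.posttest_prob,
            "fold_change": self.fold_change,
            "horizon": self.horizon,
        }


def update_risk(
    pretest_prob: float, likelihood_ratio: float, horizon: str = ""
) -> RiskEstimate:
    """Update a pre-test probability with a likelihood ratio on the odds
    scale: posttest = o·LR / (1 + o·LR) with o = p/(1−p)."""
    _check_prob(pretest_prob, "pretest_prob")
    if not likelihood_ratio > 0:
        raise DomainError(
            f"likelihood_ratio must be > 0, got {likelihood_ratio}"
        )
    odds = pretest_prob / (1.0 - pretest_prob) * likelihood_ratio
    return RiskEstimate(
        pretest_prob=pretest_prob,
        likelihood_ratio=likelihood_ratio,
        posttest_prob=odds / (1.0 + odds),
        horizon=horizon,
    )


def derive_lr(pretest_prob: float, posttest_prob: float) -> float:
    """Likelihood ratio that turns one probability into another:
    posttest odds / pretest odds.  Inverse of :func:`update_risk`."""
    _check_prob(pretest_prob, "pretest_prob")
    _check_prob(posttest_prob, "posttest_prob")
    return (posttest_prob / (1.0 - posttest_prob)) / (
        pretest_prob / (1.0 - pretest_prob)
    )


def fold_change(prob_a: float, prob_b: float) -> float:
    """Probability-scale ratio prob_a / prob_b (e.g. 0.15/0.0043 ≈ 35)."""
    _check_prob(prob_a, "prob_a")
    _check_prob(prob_b, "prob_b")
    return prob_a / prob_b


def chain_tests(
    pretest_prob: float, lrs: Sequence[float], horizon: str = ""
) -> RiskEstimate:
    """Apply a sequence of likelihood ratios in order.

    Assumes the tests are conditionally independent given outcome status,
    so the chain equals a single update with the product of the LRs; an
    empty chain returns the pre-test probability unchanged (LR 1).
    """
    _check_prob(pretest_prob, "pretest_prob")
    for i, lr in enumerate(lrs):
        if not lr > 0:
            raise DomainError(f"likelihood ratio #{i} must be > 0, got {lr}")
    product = math.prod(lrs) if lrs else 1.0
    return update_risk(pretest_prob, product, horizon=horizon)


def apply_relative_risk(
    baseline_risk: float, rr: float, scale: str = "risk"
) -> float:
    """Approximate absolute risk implied by a relative risk.

    ``scale="risk"`` multiplies on the probability scale, capped at 1 —
    a first-order approximation adequate for rare outcomes.
    ``scale="odds"`` treats ``rr`` as an odds multiplier, which keeps the
    result inside (0, 1) and is exact when the RR is really an odds ratio.
    There is no canonical link between a score's equivalent RR and an
    absolute baseline risk; both conventions are exposed so callers can
    state the one they use.
    """
    _check_prob(baseline_risk, "baseline_risk")
    if not rr > 0:
        raise DomainError(f"rr must be > 0, got {rr}")
    if scale == "risk":
        return min(baseline_risk * rr, 1.0)
    if scale == "odds":
        return update_risk(baseline_risk, rr).posttest_prob
    raise DomainError(f"scale must be 'risk' or 'odds', got {scale!r}")
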