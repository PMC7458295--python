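"""Pauker-Kassirer testing threshold for a screening test.

The testing threshold is the pre-test probability of disease above which
applying the test (and acting on a positive result) is worthwhile, given the
test's positive likelihood ratio LR+ and the benefit-to-risk ratio B/R of
treating a true case versus acting on a false positive. In odds form the
threshold probability p_t solves

    odds(p_t) * LR+ * (B/R) = 1   =>   p_t = 1 / (1 + LR+ * B/R).

Equivalently, parameterized by sensitivity and specificity,
p_t = (1-Sp) / [(1-Sp) + Se * B/R]. With LR+ = 5 and B/R = 5 the threshold
is 1/26 ~= 0.0385: screening pays off wherever preterm prevalence exceeds
about 3.85%.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ThresholdResult", "testing_threshold", "testing_threshold_from_se_sp"]


@dataclass(frozen=True)
class ThresholdResult:
    testing_threshold: float
    lr_pos: float
    benefit_risk: float


def testing_threshold(lr_pos: float, benefit_risk: float) -> ThresholdResult:
    """Threshold pre-test probability 1 / (1 + LR+ * B/R)."""
    if not lr_pos > 0:
        raise ValueError(f"lr_pos must be > 0, got {lr_pos!r}")
    if not benefit_risk > 0:
        raise ValueError(f"benefit_risk must be > 0, got {benefit_risk!r}")
    return ThresholdResult(
        testing_threshold=1.0 / (1.0 + lr_pos * benefit_risk),
        lr_pos=lr_pos,
        benefit_risk=benefit_risk,
    )


def testing_threshold_from_se_sp(
    sensitivity: float, specificity: float, benefit_risk: float
) -> ThresholdResult:
    """Same threshold from (Se, Sp): (1-Sp) / [(1-Sp) + Se * B/R]."""
    if not 0.0 < sensitivity <= 1.0:
        raise ValueError(f"sensitivity must lie in (0, 1], got {sensitivity!r}")
    if not 0.0 <= specificity < 1.0:
        raise ValueError(f"specificity must lie in [0, 1), got {specificity!r}")
    lr_pos = sensitivity / (1.0 - specificity)
    return testing_threshold(lr_pos, benefit_risk)
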