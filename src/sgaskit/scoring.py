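"""Four-item simplified gestational-age score (T-SGAS).

The score sums four maturity items read off a newborn within 24 hours of
birth -- posture, skin texture, breast development and genital development.
Each item has its own closed integer range; the total therefore lies in
[-3, 17]. Low totals indicate prematurity: a newborn is called *preterm*
when the total falls strictly below a cut-off. Two cut-off conventions are
in circulation: the original app rule (<14) and the data-driven cut-off
(<13); the latter is the package default, the former is one config flag
away.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

__all__ = [
    "ITEM_RANGES",
    "TOTAL_RANGE",
    "DEFAULT_CUTOFF",
    "APP_CUTOFF",
    "ItemScores",
    "TSGASResult",
    "total_score",
    "classify",
    "score_and_classify",
]

#: Closed integer range for each maturity item.
ITEM_RANGES: dict[str, tuple[int, int]] = {
    "posture": (0, 4),
    "skin": (-1, 5),
    "breast": (-1, 4),
    "genitals": (-1, 4),
}

#: Attainable range of the total score (sum of item minima / maxima).
TOTAL_RANGE: tuple[int, int] = (
    sum(lo for lo, _ in ITEM_RANGES.values()),
    sum(hi for _, hi in ITEM_RANGES.values()),
)

#: Data-driven cut-off: total < 13 => preterm.
DEFAULT_CUTOFF: int = 13
#: Original app rule: total < 14 => preterm.
APP_CUTOFF: int = 14

PRETERM = "preterm"
TERM = "term"


class ItemValidationError(ValueError):
    """An item score falls outside its allowed range."""


@dataclass(frozen=True)
class ItemScores:
    """One assessor's four item scores for one newborn."""

    posture: int
    skin: int
    breast: int
    genitals: int

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = ITEM_RANGES[f.name]
            v = getattr(self, f.name)
            if not (isinstance(v, (int,)) and not isinstance(v, bool)):
                raise ItemValidationError(
                    f"{f.name} must be an integer in [{lo}, {hi}], got {v!r}"
                )
            if not lo <= v <= hi:
                raise ItemValidationError(
                    f"{f.name}={v} outside allowed range [{lo}, {hi}]"
                )

    def total(self) -> int:
        return self.posture + self.skin + self.breast + self.genitals


@dataclass(frozen=True)
class TSGASResult:
    """Total score plus its dichotomous gestational-age category."""

    total: int
    category: str
    cutoff_used: int


def total_score(items: ItemScores) -> int:
    """Sum of the four item scores (exact integer in [-3, 17])."""
    return items.total()


def classify(total: float, cutoff: int = DEFAULT_CUTOFF) -> str:
    """Dichotomize a total score: ``preterm`` iff ``total < cutoff``.

    ``total`` may be a half-integer (average of two assessors); the same
    strict inequality applies.
    """
    lo, hi = TOTAL_RANGE
    if not lo <= cutoff <= hi + 1:
        raise ValueError(f"cutoff={cutoff} outside [{lo}, {hi + 1}]")
    return PRETERM if total < cutoff else TERM


def score_and_classify(items: ItemScores, cutoff: int = DEFAULT_CUTOFF) -> TSGASResult:
    t = total_score(items)
    return TSGASResult(total=t, category=classify(t, cutoff), cutoff_used=cutoff)
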