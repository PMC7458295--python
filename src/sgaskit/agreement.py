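"""Inter-observer agreement between paired score assessments.

Three complementary views, matching how agreement is usually reported for
paired maturity scores from rotating assessor pairs:

* Lin's concordance correlation coefficient (CCC) on the raw totals --
  penalizes both scatter around and departure from the identity line;
* Fleiss' kappa with pooled category marginals, applied (a) to the binned
  absolute score difference and (b) to the dichotomous preterm/term calls;
* the raw distribution of absolute score differences (0 / 1 / 2 / 3 / 4+).

The pooled-marginal Fleiss estimator is the right chance correction when
each subject is rated by two assessors drawn from a rotating pool, since no
fixed rater margins exist for a Cohen-style correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Estimate",
    "AgreementReport",
    "DegenerateInputError",
    "lin_ccc",
    "fleiss_kappa",
    "agreement_table",
    "agreement_report",
]

DIFF_BIN_LABELS = ("0", "1", "2", "3", "4+")


class DegenerateInputError(ValueError):
    """The statistic is undefined on this input (0/0 form)."""


@dataclass(frozen=True)
class Estimate:
    value: float
    ci_low: float
    ci_high: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.value, self.ci_low, self.ci_high)


@dataclass(frozen=True)
class AgreementReport:
    ccc: Estimate
    kappa_scores: Estimate
    kappa_dichotomous: Estimate
    difference_distribution: dict[str, tuple[int, float]]  # label -> (count, pct)
    n: int


def lin_ccc(x, y, *, alpha: float = 0.05) -> Estimate:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (mu_x - mu_y)^2), with population
    (1/n) moments. The CI transforms rho_c with arctanh, uses Lin's
    large-sample SE on the z scale, and back-transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise DegenerateInputError(
            "CCC undefined: both sequences constant with equal means (0/0)"
        )
    ccc = 2.0 * sxy / denom

    if sx2 == 0.0 or sy2 == 0.0 or abs(ccc) >= 1.0 - 1e-12:
        # Pearson r (needed by the variance) is undefined, or the z
        # transform blows up; report a point estimate with a degenerate CI.
        return Estimate(float(ccc), float(ccc), float(ccc))

    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location-shift relative to scale
    c2 = ccc * ccc
    # Lin (1989) variance of arctanh(rho_c)
    var_z = (
        (1 - r * r) * c2 / ((1 - c2) * r * r)
        + 4 * ccc**3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r * r * (1 - c2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = np.arctanh(ccc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(var_z)
    return Estimate(float(ccc), float(np.tanh(z - half)), float(np.tanh(z + half)))


def fleiss_kappa(ratings, categories=None, *, alpha: float = 0.05) -> Estimate:
    """Fleiss' kappa for an n-subject x m-rater matrix of category labels.

    kappa = (P_bar - P_e) / (1 - P_e) with pooled category marginals; the CI
    uses the Fleiss-Nee-Landis large-sample variance.
    """
    ratings = np.asarray(ratings)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-d subject x rater matrix")
    n, m = ratings.shape
    if m < 2:
        raise ValueError(f"need at least 2 raters, got {m}")
    if categories is None:
        categories = sorted({v for v in ratings.ravel().tolist()})
    categories = list(categories)
    cat_index = {c: j for j, c in enumerate(categories)}
    bad = {v for v in ratings.ravel().tolist()} - set(categories)
    if bad:
        raise ValueError(f"ratings contain values outside the category set: {sorted(map(str, bad))}")

    counts = np.zeros((n, len(categories)), dtype=float)
    for j, c in enumerate(categories):
        counts[:, j] = (ratings == c).sum(axis=1)

    p_j = counts.sum(axis=0) / (n * m)
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0 - 1e-12:
        raise DegenerateInputError(
            "Fleiss kappa undefined: all raters always use a single category (P_e = 1)"
        )
    p_i = (np.sum(counts**2, axis=1) - m) / (m * (m - 1))
    p_bar = float(p_i.mean())
    kappa = (p_bar - p_e) / (1 - p_e)

    # Fleiss, Nee & Landis (1979) large-sample variance
    var = (
        2.0
        / (n * m * (m - 1))
        * (p_e - (2 * m - 3) * p_e**2 + 2 * (m - 2) * float(np.sum(p_j**3)))
        / (1 - p_e) ** 2
    )
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var, 0.0))
    return Estimate(float(kappa), float(kappa - half), float(min(kappa + half, 1.0)))


def agreement_table(score1, score2) -> dict[str, tuple[int, float]]:
    """Distribution of |score1 - score2| over bins 0 / 1 / 2 / 3 / 4+.

    Returns ``{bin label: (count, percent of n)}``.
    """
    s1 = np.asarray(score1)
    s2 = np.asarray(score2)
    if s1.shape != s2.shape:
        raise ValueError("score sequences must have equal length")
    d = np.abs(s1 - s2)
    n = d.size
    bins = [int(np.sum(d == k)) for k in (0, 1, 2, 3)]
    bins.append(int(np.sum(d >= 4)))
    return {
        label: (c, 100.0 * c / n if n else float("nan"))
        for label, c in zip(DIFF_BIN_LABELS, bins)
    }


def binned_differences(score1, score2) -> np.ndarray:
    """|difference| capped at 4, the rating scale used for kappa on scores."""
    d = np.abs(np.asarray(score1) - np.asarray(score2))
    return np.minimum(d, 4)


def agreement_report(
    score1, score2, *, cutoff: int, preterm_label: str = "preterm", term_label: str = "term"
) -> AgreementReport:
    """Full agreement panel for two paired assessments of the same newborns.

    Kappa on scores treats the two assessors' totals as two categorical
    ratings on the full score scale (pooled marginals, so it is valid under
    rotating assessor pairs); kappa on the dichotomous calls treats the two
    preterm/term classifications as the two ratings. The |difference|
    distribution is reported alongside.
    """
    s1 = np.asarray(score1)
    s2 = np.asarray(score2)
    ccc = lin_ccc(s1, s2)
    score_cats = sorted(set(s1.tolist()) | set(s2.tolist()))
    kappa_scores = fleiss_kappa(np.stack([s1, s2], axis=1), categories=score_cats)
    calls1 = np.where(s1 < cutoff, preterm_label, term_label)
    calls2 = np.where(s2 < cutoff, preterm_label, term_label)
    kappa_dich = fleiss_kappa(
        np.stack([calls1, calls2], axis=1), categories=[preterm_label, term_label]
    )
    return AgreementReport(
        ccc=ccc,
        kappa_scores=kappa_scores,
        kappa_dichotomous=kappa_dich,
        difference_distribution=agreement_table(s1, s2),
        n=int(s1.size),
    )
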