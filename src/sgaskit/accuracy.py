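"""Screening accuracy of the dichotomized score against imperfect references.

Because no gold standard for gestational age exists at birth, preterm status
is labelled by four reference-standard combinations -- LMP alone, USG alone,
their union and their intersection (GA < 37 weeks, strict) -- and the score's
two-by-two performance is summarized per standard and per assessor:
prevalence, sensitivity, specificity, predictive values (Wilson CIs) and
likelihood ratios (log-method CIs). ROC/AUC uses the Mann-Whitney
concordance probability with DeLong variance; confounding by facility, sex
or maternal age is probed with stratified Mantel-Haenszel pooled odds
ratios and the Breslow-Day homogeneity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.proportion import proportion_confint

from .synthetic import NeonateRecord

__all__ = [
    "REFERENCE_KINDS",
    "ReferenceStandard",
    "TwoByTwo",
    "MetricEstimate",
    "DiagnosticSummary",
    "MantelHaenszelResult",
    "reference_labels",
    "two_by_two",
    "two_by_two_from_rates",
    "diagnostic_summary",
    "roc_auc",
    "mantel_haenszel",
    "bonferroni_alpha",
]

REFERENCE_KINDS = ("LMP", "USG", "LMP_OR_USG", "LMP_AND_USG")


@dataclass(frozen=True)
class ReferenceStandard:
    """Which imperfect GA source(s) define 'true' preterm (< threshold weeks)."""

    kind: str
    ga_threshold: float = 37.0

    def __post_init__(self) -> None:
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"kind must be one of {REFERENCE_KINDS}, got {self.kind!r}")
        if self.ga_threshold <= 0:
            raise ValueError(f"ga_threshold must be > 0, got {self.ga_threshold!r}")


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion counts of the score's preterm call vs a reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    value: float  # percent for proportions, ratio for LRs
    ci_low: float
    ci_high: float
    flag: str | None = None  # e.g. "infinite", "undefined"


@dataclass(frozen=True)
class DiagnosticSummary:
    prevalence: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    lr_pos: MetricEstimate
    lr_neg: MetricEstimate
    counts: TwoByTwo


def reference_labels(
    records: Iterable[NeonateRecord], standard: ReferenceStandard
) -> np.ndarray:
    """Boolean preterm labels (True = preterm) under the chosen standard."""
    records = list(records)
    lmp = np.array([r.ga_lmp for r in records], dtype=float)
    usg = np.array([r.ga_usg for r in records], dtype=float)
    if np.any(np.isnan(lmp)) or np.any(np.isnan(usg)):
        raise ValueError("missing GA field (NaN) in records")
    t = standard.ga_threshold
    if standard.kind == "LMP":
        return lmp < t
    if standard.kind == "USG":
        return usg < t
    if standard.kind == "LMP_OR_USG":
        return (lmp < t) | (usg < t)
    return (lmp < t) & (usg < t)


def two_by_two(test_positive, reference_positive) -> TwoByTwo:
    """Cross-tabulate boolean test calls against boolean reference labels."""
    test = np.asarray(test_positive, dtype=bool)
    ref = np.asarray(reference_positive, dtype=bool)
    if test.shape != ref.shape:
        raise ValueError("sequences must have equal length")
    return TwoByTwo(
        tp=int(np.sum(test & ref)),
        fp=int(np.sum(test & ~ref)),
        fn=int(np.sum(~test & ref)),
        tn=int(np.sum(~test & ~ref)),
    )


def two_by_two_from_rates(n: int, prevalence_pct: float, se_pct: float, sp_pct: float) -> TwoByTwo:
    """Reconstruct integer confusion counts from printed summary rates.

    Inverts the prevalence/Se/Sp computation at total n by rounding each
    implied margin to the nearest integer; useful for checking the internal
    consistency of a published accuracy table.
    """
    diseased = round(n * prevalence_pct / 100.0)
    tp = round(diseased * se_pct / 100.0)
    healthy = n - diseased
    tn = round(healthy * sp_pct / 100.0)
    return TwoByTwo(tp=tp, fp=healthy - tn, fn=diseased - tp, tn=tn)


def _prop_ci(k: int, n: int, method: str, alpha: float) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
    return float(lo), float(hi)


def _prop_estimate(k: int, n: int, method: str, alpha: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), flag="undefined")
    lo, hi = _prop_ci(k, n, method, alpha)
    return MetricEstimate(100.0 * k / n, 100.0 * lo, 100.0 * hi)


def _lr_pos_estimate(t: TwoByTwo, zcrit: float) -> MetricEstimate:
    se = t.tp / (t.tp + t.fn)
    fpr = t.fp / (t.fp + t.tn)
    if fpr == 0.0:
        return MetricEstimate(float("inf"), float("nan"), float("nan"), flag="infinite")
    lr = se / fpr
    if t.tp == 0:
        return MetricEstimate(0.0, 0.0, float("nan"), flag="zero-numerator")
    # Simel et al. log-method SE
    se_log = math.sqrt((1 - se) / t.tp + (1 - fpr) / t.fp)
    return MetricEstimate(
        lr, lr * math.exp(-zcrit * se_log), lr * math.exp(zcrit * se_log)
    )


def _lr_neg_estimate(t: TwoByTwo, zcrit: float) -> MetricEstimate:
    se = t.tp / (t.tp + t.fn)
    sp = t.tn / (t.fp + t.tn)
    if sp == 0.0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), flag="undefined")
    lr = (1 - se) / sp
    if t.fn == 0:
        return MetricEstimate(0.0, 0.0, float("nan"), flag="zero-numerator")
    se_log = math.sqrt(se / t.fn + (1 - sp) / t.tn) if t.tn > 0 else float("nan")
    return MetricEstimate(
        lr, lr * math.exp(-zcrit * se_log), lr * math.exp(zcrit * se_log)
    )


def diagnostic_summary(
    t: TwoByTwo, *, ci_method: str = "wilson", alpha: float = 0.05
) -> DiagnosticSummary:
    """Prevalence, Se, Sp, PPV, NPV (percent) and LR+/LR- for one 2x2 table.

    ``ci_method`` is any proportion-CI method statsmodels supports
    ('wilson' default, 'beta' for exact Clopper-Pearson).
    """
    if ci_method == "clopper-pearson":
        ci_method = "beta"
    zcrit = float(stats.norm.ppf(1 - alpha / 2))
    n = t.total
    diseased = t.tp + t.fn
    healthy = t.fp + t.tn
    if diseased == 0 or healthy == 0:
        raise ValueError("both diseased and healthy margins must be positive")
    return DiagnosticSummary(
        prevalence=_prop_estimate(diseased, n, ci_method, alpha),
        sensitivity=_prop_estimate(t.tp, diseased, ci_method, alpha),
        specificity=_prop_estimate(t.tn, healthy, ci_method, alpha),
        ppv=_prop_estimate(t.tp, t.tp + t.fp, ci_method, alpha),
        npv=_prop_estimate(t.tn, t.tn + t.fn, ci_method, alpha),
        lr_pos=_lr_pos_estimate(t, zcrit),
        lr_neg=_lr_neg_estimate(t, zcrit),
        counts=t,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong structural-component variance of the Mann-Whitney AUC."""
    m, n = pos.size, neg.size
    # V10[i] = P(neg < pos_i) + 0.5 P(neg == pos_i)
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos])
    v01 = np.array([(np.sum(q < pos) + 0.5 * np.sum(q == pos)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    marker, labels, *, lower_is_positive: bool = False, alpha: float = 0.05
) -> MetricEstimate:
    """AUC as the Mann-Whitney concordance probability (ties get 1/2 credit).

    With ``lower_is_positive`` the marker is negated first (low maturity
    scores indicate preterm). For a monotone univariate logistic model the
    predicted-probability AUC equals this raw-marker AUC. CI: DeLong
    variance, normal interval, clipped to [0, 1]; degenerate variance falls
    back to a seeded bootstrap.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("marker and labels must have equal length")
    if lower_is_positive:
        x = -x
    pos, neg = x[y], x[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (pos.size * neg.size)

    var = _delong_variance(pos, neg, auc)
    if var <= 0.0 or not np.isfinite(var):
        # all structural components identical (e.g. constant marker)
        rng = np.random.default_rng(0)
        idx_p = rng.integers(0, pos.size, size=(200, pos.size))
        idx_n = rng.integers(0, neg.size, size=(200, neg.size))
        boots = []
        for bp, bn in zip(idx_p, idx_n):
            p, q = pos[bp], neg[bn]
            g = (p[:, None] > q[None, :]).sum()
            t_ = (p[:, None] == q[None, :]).sum()
            boots.append((g + 0.5 * t_) / (p.size * q.size))
        lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return MetricEstimate(float(auc), float(lo), float(hi), flag="bootstrap-ci")
    half = stats.norm.ppf(1 - alpha / 2) * math.sqrt(var)
    return MetricEstimate(
        float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))
    )


# ---------------------------------------------------------------------------
# Stratified Mantel-Haenszel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelHaenszelResult:
    pooled_or: float
    ci_low: float
    ci_high: float
    breslow_day_stat: float
    breslow_day_pvalue: float
    n_strata: int
    corrected_strata: tuple[int, ...]  # indices that received a 0.5 correction


def mantel_haenszel(
    strata: Sequence[TwoByTwo], *, alpha: float = 0.05
) -> MantelHaenszelResult:
    """Pooled odds ratio across strata with RBG CI and Breslow-Day test.

    Strata with a zero cell receive a 0.5 continuity correction (that
    stratum only) and are flagged in the result.
    """
    if len(strata) == 0:
        raise ValueError("need at least one stratum")
    tables = []
    corrected = []
    for i, t in enumerate(strata):
        cells = np.array([[t.tp, t.fp], [t.fn, t.tn]], dtype=float)
        if (cells == 0).any():
            cells = cells + 0.5
            corrected.append(i)
        tables.append(cells)
    if len(corrected) == len(strata) and all(
        (np.array([[t.tp, t.fp], [t.fn, t.tn]]) == 0).sum() >= 2 for t in strata
    ):
        raise ValueError("all strata degenerate (multiple zero margins)")
    st = StratifiedTable(tables)
    pooled = float(st.oddsratio_pooled)
    lo, hi = st.oddsratio_pooled_confint(alpha=alpha)
    if len(strata) > 1:
        bd = st.test_equal_odds(adjust=False)
        bd_stat, bd_p = float(bd.statistic), float(bd.pvalue)
    else:
        bd_stat, bd_p = 0.0, 1.0
    return MantelHaenszelResult(
        pooled_or=pooled,
        ci_low=float(lo),
        ci_high=float(hi),
        breslow_day_stat=bd_stat,
        breslow_day_pvalue=bd_p,
        n_strata=len(strata),
        corrected_strata=tuple(corrected),
    )


def bonferroni_alpha(global_alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance level for a family of comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return global_alpha / n_comparisons
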