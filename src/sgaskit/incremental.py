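"""Incremental predictive value of the score over birthweight (IDI / NRI).

Birthweight alone already predicts prematurity; the question is whether the
maturity score adds discrimination on top of it. Two nested logistic risk
models are fitted (old: birthweight; new: birthweight + total score) and
compared with the integrated discrimination improvement

    IDI = [mean(p_new | event) - mean(p_old | event)]
        - [mean(p_new | nonevent) - mean(p_old | nonevent)]

(equivalently the difference of the models' discrimination slopes) and the
net reclassification improvement, continuous by default

    NRI = [P(up | event) - P(down | event)] + [P(down | nonevent) - P(up | nonevent)]

or category-based when risk thresholds are supplied. Asymptotic
(paired-difference) confidence intervals by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RiskModelFit",
    "ReclassificationReport",
    "SeparationError",
    "fit_logistic",
    "idi",
    "nri",
    "incremental_value",
]


class SeparationError(RuntimeError):
    """The logistic MLE does not exist (complete or quasi-complete separation)."""


@dataclass(frozen=True)
class RiskModelFit:
    coefficients: dict[str, float]  # includes "intercept"
    fitted_probs: np.ndarray
    converged: bool
    loglik: float


@dataclass(frozen=True)
class ReclassificationReport:
    idi: tuple[float, float, float]  # estimate, ci_low, ci_high
    nri_continuous: tuple[float, float, float]
    nri_categorical: tuple[float, float, float] | None = None
    thresholds: tuple[float, ...] | None = None


def fit_logistic(predictors, outcome, *, names=None) -> RiskModelFit:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels).

    ``predictors`` is an n x p matrix (an intercept is added internally) or
    an empty-column matrix for an intercept-only model. Raises
    SeparationError when the fitted probabilities perfectly separate the
    outcome (the MLE diverges).
    """
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if n != y.size:
        raise ValueError("predictors and outcome must have equal length")
    if n <= p:
        raise ValueError(f"need n > number of predictors ({p}), got n={n}")
    if not (y.any() and (1 - y).any()):
        raise ValueError("outcome must contain both classes")
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-10)
        except Exception as exc:  # statsmodels raises on perfect separation
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                raise SeparationError(str(exc)) from exc
            raise
    probs = np.asarray(res.predict(design))
    eps = 1e-8
    if np.all((probs > 1 - eps) == (y == 1)) and np.all((probs < eps) == (y == 0)) and p > 0:
        raise SeparationError("complete separation: fitted probabilities are 0/1")
    grad = design.T @ (y - probs)
    coefs = {"intercept": float(res.params[0])}
    coefs.update({nm: float(b) for nm, b in zip(names, res.params[1:])})
    return RiskModelFit(
        coefficients=coefs,
        fitted_probs=np.clip(probs, 1e-12, 1 - 1e-12),
        converged=bool(res.mle_retvals.get("converged", True)) and float(np.abs(grad).max()) < 1e-4,
        loglik=float(res.llf),
    )


def _split(p_old, p_new, outcome):
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if not (p_old.shape == p_new.shape == y.shape):
        raise ValueError("sequences must have equal length")
    if not (y.any() and (~y).any()):
        raise ValueError("outcome must contain both classes")
    return p_old, p_new, y


def idi(p_old, p_new, outcome, *, alpha: float = 0.05) -> tuple[float, float, float]:
    """Integrated discrimination improvement with a paired-difference CI."""
    p_old, p_new, y = _split(p_old, p_new, outcome)
    d = p_new - p_old
    d_e, d_ne = d[y], d[~y]
    est = float(d_e.mean() - d_ne.mean())
    se = np.sqrt(
        (d_e.var(ddof=1) / d_e.size if d_e.size > 1 else 0.0)
        + (d_ne.var(ddof=1) / d_ne.size if d_ne.size > 1 else 0.0)
    )
    half = float(stats.norm.ppf(1 - alpha / 2) * se)
    return (est, est - half, est + half)


def nri(
    p_old, p_new, outcome, thresholds=None, *, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Net reclassification improvement: continuous by default, category-based
    when strictly increasing risk thresholds are given."""
    p_old, p_new, y = _split(p_old, p_new, outcome)
    if thresholds is not None:
        thresholds = tuple(thresholds)
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        old_cat = np.digitize(p_old, thresholds)
        new_cat = np.digitize(p_new, thresholds)
        move = np.sign(new_cat - old_cat)
    else:
        move = np.sign(p_new - p_old)
    m_e, m_ne = move[y], move[~y]
    nri_e = float(m_e.mean())
    nri_ne = float(-m_ne.mean())
    est = nri_e + nri_ne
    var = (m_e.var(ddof=1) / m_e.size if m_e.size > 1 else 0.0) + (
        m_ne.var(ddof=1) / m_ne.size if m_ne.size > 1 else 0.0
    )
    half = float(stats.norm.ppf(1 - alpha / 2) * np.sqrt(var))
    return (est, est - half, est + half)


def incremental_value(
    birthweight, score, outcome, *, thresholds=None, alpha: float = 0.05
) -> ReclassificationReport:
    """IDI/NRI of adding the total score to a birthweight-only risk model."""
    bw = np.asarray(birthweight, dtype=float)
    sc = np.asarray(score, dtype=float)
    old = fit_logistic(bw[:, None], outcome, names=["birthweight"])
    new = fit_logistic(np.column_stack([bw, sc]), outcome, names=["birthweight", "score"])
    report = ReclassificationReport(
        idi=idi(old.fitted_probs, new.fitted_probs, outcome, alpha=alpha),
        nri_continuous=nri(old.fitted_probs, new.fitted_probs, outcome, alpha=alpha),
        nri_categorical=(
            nri(old.fitted_probs, new.fitted_probs, outcome, thresholds, alpha=alpha)
            if thresholds is not None
            else None
        ),
        thresholds=tuple(thresholds) if thresholds is not None else None,
    )
    return report


def discrimination_slope(probs, outcome) -> float:
    """mean(p | event) - mean(p | nonevent); IDI = slope(new) - slope(old)."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    return float(p[y].mean() - p[~y].mean())
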