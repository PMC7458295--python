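"""Hui-Walter latent-class model for diagnostic tests without a gold standard.

With J >= 3 binary tests applied to one population and assumed conditionally
independent given the true (latent) disease state, the prevalence pi and
every test's sensitivity Se_j and specificity Sp_j are identifiable from the
2^J response-pattern counts alone (2^J - 1 >= 2J + 1 degrees of freedom).
Here the three "tests" are typically the maturity score's preterm call, LMP
dating and USG dating, none of which is a true reference.

The likelihood of pattern y = (y_1..y_J) is

    P(y) = pi * prod_j Se_j^{y_j} (1-Se_j)^{1-y_j}
         + (1-pi) * prod_j (1-Sp_j)^{y_j} Sp_j^{1-y_j}

maximized by EM: the E-step computes each pattern's posterior probability of
the diseased class, the M-step re-estimates (pi, Se, Sp) as weighted
proportions. The likelihood never decreases across iterations. Multiple
random starts guard against local maxima; label switching (the mirrored
solution pi -> 1-pi, Se <-> 1-Sp) is resolved by requiring Se_j + Sp_j >= 1
for the majority of tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatternCounts",
    "LCFit",
    "ModelSpecificationError",
    "lc_loglik",
    "fit_hui_walter",
    "patterns_from_binary_matrix",
    "simulate_pattern_counts",
]


class ModelSpecificationError(ValueError):
    """The latent-class model is not identifiable on this input."""


@dataclass(frozen=True)
class PatternCounts:
    """Counts of the 2^J binary response patterns of J tests.

    Pattern order: lexicographic over (y_1, ..., y_J) with y_1 the slowest
    bit, i.e. index = sum_j y_j * 2^(J-1-j).
    """

    j: int
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.j < 1:
            raise ValueError("j must be >= 1")
        if len(self.counts) != 2**self.j:
            raise ValueError(f"need {2**self.j} counts for J={self.j}, got {len(self.counts)}")
        if min(self.counts) < 0:
            raise ValueError("counts must be non-negative")
        if sum(self.counts) <= 0:
            raise ValueError("total count must be positive")

    @property
    def n(self) -> float:
        return float(sum(self.counts))

    def pattern_matrix(self) -> np.ndarray:
        """2^J x J 0/1 matrix of response patterns, row order matching counts."""
        return np.array(list(itertools.product((0, 1), repeat=self.j)), dtype=float)

    def permute_tests(self, order: tuple[int, ...]) -> "PatternCounts":
        pats = self.pattern_matrix().astype(int)
        new_counts = [0.0] * len(self.counts)
        for idx, pat in enumerate(pats):
            new_pat = pat[list(order)]
            new_idx = int(sum(b * 2 ** (self.j - 1 - k) for k, b in enumerate(new_pat)))
            new_counts[new_idx] = self.counts[idx]
        return PatternCounts(self.j, tuple(new_counts))


def patterns_from_binary_matrix(tests) -> PatternCounts:
    """Tally an n x J 0/1 per-record matrix into pattern counts."""
    m = np.asarray(tests, dtype=int)
    if m.ndim != 2:
        raise ValueError("tests must be an n x J matrix")
    n, j = m.shape
    idx = m @ (2 ** np.arange(j - 1, -1, -1))
    counts = np.bincount(idx, minlength=2**j).astype(float)
    return PatternCounts(j, tuple(counts))


def _pattern_class_probs(
    pats: np.ndarray, se: np.ndarray, sp: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    a = np.prod(se**pats * (1 - se) ** (1 - pats), axis=1)  # P(y | diseased)
    b = np.prod((1 - sp) ** pats * sp ** (1 - pats), axis=1)  # P(y | healthy)
    return a, b


def lc_loglik(pi: float, se, sp, counts: PatternCounts) -> float:
    """Multinomial log-likelihood of pattern counts under (pi, Se, Sp).

    Returns -inf when a zero-probability pattern has a positive count.
    """
    se = np.asarray(se, dtype=float)
    sp = np.asarray(sp, dtype=float)
    if not (0.0 <= pi <= 1.0) or np.any(se < 0) or np.any(se > 1) or np.any(sp < 0) or np.any(sp > 1):
        raise ValueError("parameters must lie in [0, 1]")
    if se.size != counts.j or sp.size != counts.j:
        raise ValueError(f"need {counts.j} Se and Sp values")
    pats = counts.pattern_matrix()
    a, b = _pattern_class_probs(pats, se, sp)
    p = pi * a + (1 - pi) * b
    c = np.asarray(counts.counts, dtype=float)
    if np.any((p == 0) & (c > 0)):
        return float("-inf")
    with np.errstate(divide="ignore"):
        lp = np.where(c > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    return float(np.sum(c * lp))


@dataclass(frozen=True)
class LCFit:
    pi: float
    se: tuple[float, ...]
    sp: tuple[float, ...]
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool
    pi_ci: tuple[float, float] | None = None
    se_ci: tuple[tuple[float, float], ...] | None = None
    sp_ci: tuple[tuple[float, float], ...] | None = None

    @property
    def lr_pos(self) -> tuple[float, ...]:
        return tuple(
            s / (1 - p) if p < 1 else float("inf") for s, p in zip(self.se, self.sp)
        )

    @property
    def lr_neg(self) -> tuple[float, ...]:
        return tuple(
            (1 - s) / p if p > 0 else float("nan") for s, p in zip(self.se, self.sp)
        )


def _em(
    counts_arr: np.ndarray,
    pats: np.ndarray,
    pi0: float,
    se0: np.ndarray,
    sp0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, np.ndarray, float, int, bool]:
    n = counts_arr.sum()
    pi, se, sp = pi0, se0.copy(), sp0.copy()
    prev_ll = -np.inf
    eps = 1e-300
    for it in range(1, max_iter + 1):
        a, b = _pattern_class_probs(pats, se, sp)
        p = pi * a + (1 - pi) * b
        p = np.maximum(p, eps)
        ll = float(np.sum(counts_arr * np.log(p)))
        # EM guarantee; a violation means a defect, not data trouble
        assert ll >= prev_ll - 1e-9, "EM log-likelihood decreased"
        if ll - prev_ll < tol and it > 1:
            return pi, se, sp, ll, it, True
        prev_ll = ll
        w = pi * a / p  # posterior P(diseased | pattern)
        cw = counts_arr * w
        n1 = cw.sum()
        n0 = n - n1
        pi = n1 / n
        if n1 > 0:
            se = (cw @ pats) / n1
        if n0 > 0:
            sp = ((counts_arr - cw) @ (1 - pats)) / n0
        se = np.clip(se, 0.0, 1.0)
        sp = np.clip(sp, 0.0, 1.0)
    return pi, se, sp, prev_ll, max_iter, False


def _resolve_labels(pi, se, sp):
    """Enforce Se_j + Sp_j >= 1 for the majority of tests (swap classes if not)."""
    if np.sum(se + sp < 1.0) > se.size / 2:
        return 1.0 - pi, 1.0 - sp, 1.0 - se
    return pi, se, sp


def fit_hui_walter(
    counts: PatternCounts,
    *,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = 12345,
    ci: str = "bootstrap",
    n_boot: int = 500,
    alpha: float = 0.05,
) -> LCFit:
    """Maximum-likelihood Hui-Walter fit by EM over random restarts.

    ``ci`` is 'bootstrap' (multinomial resampling of the pattern counts,
    refitting from the point estimate) or 'none'. Boundary solutions (any
    parameter within 1e-6 of 0/1) are flagged.
    """
    if counts.j < 3:
        raise ModelSpecificationError(
            f"single-population identifiability needs J >= 3 tests, got J={counts.j}"
        )
    rng = np.random.default_rng(seed)
    pats = counts.pattern_matrix()
    c = np.asarray(counts.counts, dtype=float)

    best = None
    for s in range(n_starts):
        if s == 0:
            # moment-flavoured start: marginal positivity rates
            pos = (c @ pats) / c.sum()
            pi0 = float(np.clip(pos.mean(), 0.05, 0.95))
            se0 = np.clip(pos + 0.3, 0.55, 0.95)
            sp0 = np.clip(1 - pos + 0.0, 0.55, 0.95)
        else:
            pi0 = rng.uniform(0.02, 0.98)
            se0 = rng.uniform(0.5, 0.99, size=counts.j)
            sp0 = rng.uniform(0.5, 0.99, size=counts.j)
        fit = _em(c, pats, pi0, se0, sp0, tol, max_iter)
        if best is None or fit[3] > best[3]:
            best = fit
    pi, se, sp, ll, n_iter, converged = best
    pi, se, sp = _resolve_labels(pi, np.asarray(se), np.asarray(sp))
    boundary = bool(
        min(pi, 1 - pi) < 1e-6
        or np.any(np.minimum(se, 1 - se) < 1e-6)
        or np.any(np.minimum(sp, 1 - sp) < 1e-6)
    )

    pi_ci = se_ci = sp_ci = None
    if ci == "bootstrap":
        n = int(round(counts.n))
        probs = c / c.sum()
        boot_pi = np.empty(n_boot)
        boot_se = np.empty((n_boot, counts.j))
        boot_sp = np.empty((n_boot, counts.j))
        for bidx in range(n_boot):
            bc = rng.multinomial(n, probs).astype(float)
            if bc.sum() == 0:
                bc = c
            bpi, bse, bsp, _, _, _ = _em(
                bc, pats, pi, np.asarray(se), np.asarray(sp), tol, max_iter
            )
            bpi, bse, bsp = _resolve_labels(bpi, np.asarray(bse), np.asarray(bsp))
            boot_pi[bidx] = bpi
            boot_se[bidx] = bse
            boot_sp[bidx] = bsp
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        pi_ci = tuple(float(q) for q in np.percentile(boot_pi, qs))
        se_ci = tuple(
            (float(lo), float(hi))
            for lo, hi in zip(*np.percentile(boot_se, qs, axis=0))
        )
        sp_ci = tuple(
            (float(lo), float(hi))
            for lo, hi in zip(*np.percentile(boot_sp, qs, axis=0))
        )
    elif ci != "none":
        raise ValueError(f"ci must be 'bootstrap' or 'none', got {ci!r}")

    return LCFit(
        pi=float(pi),
        se=tuple(float(v) for v in se),
        sp=tuple(float(v) for v in sp),
        loglik=float(ll),
        n_iter=int(n_iter),
        converged=bool(converged),
        boundary=boundary,
        pi_ci=pi_ci,
        se_ci=se_ci,
        sp_ci=sp_ci,
    )


def simulate_pattern_counts(
    pi: float, se, sp, n: int, rng: np.random.Generator
) -> PatternCounts:
    """Draw pattern counts from the latent-class model itself."""
    se = np.asarray(se, dtype=float)
    sp = np.asarray(sp, dtype=float)
    j = se.size
    pats = np.array(list(itertools.product((0, 1), repeat=j)), dtype=float)
    a, b = _pattern_class_probs(pats, se, sp)
    probs = pi * a + (1 - pi) * b
    counts = rng.multinomial(n, probs / probs.sum())
    return PatternCounts(j, tuple(float(x) for x in counts))
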