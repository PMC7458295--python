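"""Classification-tree discovery of risk groups and score cut-offs.

A small, deterministic CART: greedy binary recursive partitioning of a
binary outcome (preterm / term) on ordered predictors (birthweight in kg
and the total maturity score), choosing at each node the split that most
reduces impurity. Deviance impurity is the default -- the convention of the
classic R tree grower -- with Gini as an option. Candidate thresholds are
midpoints between sorted distinct predictor values, so splits on an integer
score land on half-integers; ``extract_cutoffs`` snaps those back to the
integer cut-off c such that "score < c" reproduces the split.

No pruning or cross-validation: the clinical use case is a single small,
readable tree (typically depth <= 4 yielding a handful of risk groups
ordered by preterm probability).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["CARTConfig", "CARTNode", "fit_cart", "extract_cutoffs", "best_single_split"]


@dataclass(frozen=True)
class CARTConfig:
    impurity: str = "deviance"  # or "gini"
    min_split: int = 20  # smallest node eligible for splitting
    min_leaf: int = 7  # smallest allowed child
    max_depth: int = 4

    def __post_init__(self) -> None:
        if self.impurity not in ("deviance", "gini"):
            raise ValueError(f"impurity must be 'deviance' or 'gini', got {self.impurity!r}")
        if self.min_leaf < 1:
            raise ValueError(f"min_leaf must be >= 1, got {self.min_leaf}")
        if self.min_split < 2:
            raise ValueError(f"min_split must be >= 2, got {self.min_split}")
        if self.max_depth < 1:
            raise ValueError(f"max_depth must be >= 1, got {self.max_depth}")


@dataclass
class CARTNode:
    """One node: a split ("var < threshold" goes left) or a leaf."""

    n: int
    p_preterm: float
    split_var: str | None = None
    split_threshold: float | None = None
    left: "CARTNode | None" = None
    right: "CARTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def predict_one(self, x: dict[str, float]) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.split_var] < node.split_threshold else node.right
        return node.p_preterm

    def leaves(self) -> list["CARTNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {"n": self.n, "p_preterm": self.p_preterm}
        if not self.is_leaf:
            d["split_var"] = self.split_var
            d["split_threshold"] = self.split_threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf: n={self.n} p_preterm={self.p_preterm:.4f}"
        lines = [
            f"{pad}{self.split_var} < {self.split_threshold:g} "
            f"(n={self.n}, p_preterm={self.p_preterm:.4f})",
            self.left.to_text(indent + 1),
            self.right.to_text(indent + 1),
        ]
        return "\n".join(lines)


def _impurity_fn(kind: str) -> Callable[[int, int], float]:
    # node impurity from (n, n_positive); both return a size-weighted value so
    # that child impurities simply add
    if kind == "gini":
        def gini(n: int, k: int) -> float:
            if n == 0:
                return 0.0
            p = k / n
            return 2.0 * n * p * (1.0 - p)

        return gini

    def deviance(n: int, k: int) -> float:
        if n == 0:
            return 0.0
        dev = 0.0
        for c in (k, n - k):
            if c > 0:
                dev -= 2.0 * c * np.log(c / n)
        return dev

    return deviance


def best_single_split(
    X: dict[str, np.ndarray], y: np.ndarray, config: CARTConfig
) -> tuple[str, float, float] | None:
    """Best (variable, threshold, impurity decrease) over all candidates.

    Candidate thresholds are midpoints between consecutive distinct values;
    a candidate is admissible when both children have >= min_leaf records.
    Returns None when no candidate has a positive impurity decrease.
    Ties break toward the first variable in insertion order, then toward the
    smaller threshold (deterministic).
    """
    imp = _impurity_fn(config.impurity)
    n = y.size
    k = int(y.sum())
    parent = imp(n, k)
    best: tuple[str, float, float] | None = None
    for var, values in X.items():
        order = np.argsort(values, kind="stable")
        v = values[order]
        ys = y[order].astype(int)
        cum_k = np.cumsum(ys)
        distinct_boundary = np.nonzero(np.diff(v) > 0)[0]  # split after index i
        for i in distinct_boundary:
            n_left = i + 1
            n_right = n - n_left
            if n_left < config.min_leaf or n_right < config.min_leaf:
                continue
            k_left = int(cum_k[i])
            gain = parent - imp(n_left, k_left) - imp(n_right, k - k_left)
            thr = (v[i] + v[i + 1]) / 2.0
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (var, float(thr), float(gain))
    return best


def fit_cart(
    features: dict[str, np.ndarray] | "object",
    outcome,
    config: CARTConfig = CARTConfig(),
) -> CARTNode:
    """Grow a classification tree on ordered predictors.

    ``features`` maps predictor name -> numeric array (a pandas DataFrame of
    numeric columns also works). ``outcome`` is boolean (True = preterm).
    A single-class outcome yields a root leaf.
    """
    if hasattr(features, "columns"):  # DataFrame
        X = {c: np.asarray(features[c], dtype=float) for c in features.columns}
    else:
        X = {k: np.asarray(v, dtype=float) for k, v in features.items()}
    y = np.asarray(outcome, dtype=bool)
    sizes = {k: v.size for k, v in X.items()}
    if len(set(sizes.values())) != 1 or y.size != next(iter(sizes.values())):
        raise ValueError("all predictors and the outcome must have equal length")

    def grow(idx: np.ndarray, depth: int) -> CARTNode:
        yi = y[idx]
        n = yi.size
        node = CARTNode(n=n, p_preterm=float(yi.mean()))
        if depth >= config.max_depth or n < config.min_split or yi.all() or not yi.any():
            return node
        split = best_single_split({k: v[idx] for k, v in X.items()}, yi, config)
        if split is None:
            return node
        var, thr, _gain = split
        mask = X[var][idx] < thr
        node.split_var = var
        node.split_threshold = thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(y.size), 0)


def extract_cutoffs(
    tree: CARTNode, *, integer_vars: tuple[str, ...] = ("score",)
) -> dict[str, list[float]]:
    """In-order list of split thresholds per variable.

    For variables named in ``integer_vars`` the midpoint threshold is snapped
    to the smallest integer >= threshold, so that "var < cutoff" reproduces
    the split on integer data. Continuous variables keep the raw midpoint.
    """
    out: dict[str, list[float]] = {}

    def walk(node: CARTNode) -> None:
        if node.is_leaf:
            return
        walk(node.left)
        thr = node.split_threshold
        if node.split_var in integer_vars:
            thr = float(np.ceil(thr))
        out.setdefault(node.split_var, []).append(thr)
        walk(node.right)

    walk(tree)
    return out
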