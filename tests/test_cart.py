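"""Recursive partitioning: splits, stopping, cut-off extraction."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

import sgaskit as sk
from sgaskit.cart import CARTNode, best_single_split


def exhaustive_depth1_split(X, y, impurity, min_leaf):
    """Independent oracle: scan every variable and midpoint directly."""

    def node_impurity(yy):
        n = yy.size
        if n == 0:
            return 0.0
        k = yy.sum()
        if impurity == "gini":
            p = k / n
            return 2.0 * n * p * (1 - p)
        dev = 0.0
        for c in (k, n - k):
            if c > 0:
                dev -= 2.0 * c * np.log(c / n)
        return dev

    parent = node_impurity(y)
    best = None
    for var, v in X.items():
        for thr in np.unique(v)[:-1]:
            distinct = np.unique(v)
            mid = (thr + distinct[distinct > thr][0]) / 2
            mask = v < mid
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            gain = parent - node_impurity(y[mask]) - node_impurity(y[~mask])
            if gain > 1e-12 and (best is None or gain > best[2] + 1e-12):
                best = (var, mid, gain)
    return best


def test_single_class_outcome_yields_root_leaf():
    tree = sk.fit_cart({"score": np.arange(50.0)}, np.zeros(50, dtype=bool))
    assert tree.is_leaf and tree.p_preterm == 0.0 and tree.n == 50


def test_noiseless_birthweight_rule_recovers_flanking_threshold():
    """Outcome = (birthweight < 2.5) exactly: the first split lands between
    the two observed values flanking 2.5."""
    rng = np.random.default_rng(0)
    bw = rng.uniform(1.0, 4.0, size=400)
    score = rng.integers(-3, 18, size=400).astype(float)
    y = bw < 2.5
    tree = sk.fit_cart({"birthweight": bw, "score": score}, y)
    assert tree.split_var == "birthweight"
    below = bw[bw < 2.5].max()
    above = bw[bw >= 2.5].min()
    assert below < tree.split_threshold < above
    assert tree.left.p_preterm == 1.0 and tree.right.p_preterm == 0.0


@pytest.mark.parametrize("impurity", ["deviance", "gini"])
def test_depth1_matches_exhaustive_oracle(impurity):
    rng = np.random.default_rng(1)
    cfg = sk.CARTConfig(impurity=impurity, min_leaf=5, min_split=10, max_depth=1)
    for trial in range(25):
        n = int(rng.integers(30, 200))
        X = {
            "birthweight": rng.uniform(1, 4, size=n).round(2),
            "score": rng.integers(-3, 18, size=n).astype(float),
        }
        p = 1 / (1 + np.exp(2.5 * (X["birthweight"] - 2.5)))
        y = rng.uniform(size=n) < p
        if y.all() or not y.any():
            continue
        got = best_single_split(X, y, cfg)
        want = exhaustive_depth1_split(X, y, impurity, cfg.min_leaf)
        if want is None:
            assert got is None
            continue
        assert got[0] == want[0]
        assert got[1] == pytest.approx(want[1])
        assert got[2] == pytest.approx(want[2])


def test_depth1_gini_matches_sklearn():
    rng = np.random.default_rng(2)
    cfg = sk.CARTConfig(impurity="gini", min_leaf=1, min_split=2, max_depth=1)
    for _ in range(10):
        n = 120
        x = rng.normal(size=n)
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-2 * x))
        if y.all() or not y.any():
            continue
        tree = sk.fit_cart({"x": x}, y, cfg)
        skl = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x[:, None], y)
        if tree.is_leaf:
            continue
        # sklearn stores thresholds in float32
        assert tree.split_threshold == pytest.approx(skl.tree_.threshold[0], abs=1e-6)


def test_tree_structural_invariants(eligible_1wk):
    bw = np.array([r.birthweight for r in eligible_1wk])
    score = np.array([r.items_a1.total() for r in eligible_1wk], dtype=float)
    labels = sk.reference_labels(eligible_1wk, sk.ReferenceStandard("LMP"))
    tree = sk.fit_cart({"birthweight": bw, "score": score}, labels)

    def check(node: CARTNode):
        if node.is_leaf:
            return
        assert node.left.n + node.right.n == node.n
        # impurity never increases on an accepted split
        def dev(nn, p):
            out = 0.0
            for c in (p * nn, (1 - p) * nn):
                if c > 0:
                    out -= 2 * c * np.log(c / nn)
            return out

        assert dev(node.left.n, node.left.p_preterm) + dev(
            node.right.n, node.right.p_preterm
        ) <= dev(node.n, node.p_preterm) + 1e-9
        check(node.left)
        check(node.right)

    check(tree)
    # training predictions reproduce leaf rates exactly
    X = {"birthweight": bw, "score": score}
    preds = np.array(
        [tree.predict_one({k: v[i] for k, v in X.items()}) for i in range(len(bw))]
    )
    for leaf in tree.leaves():
        m = np.isclose(preds, leaf.p_preterm)
        assert m.sum() >= leaf.n  # ties between equal-rate leaves allowed


def test_risk_groups_ordered_like_clinical_expectation(eligible_1wk):
    """Depth-2 tree on birthweight + score: first split on birthweight, four
    risk groups, and the low-weight/low-score group carries the highest
    preterm probability."""
    bw = np.array([r.birthweight for r in eligible_1wk])
    score = np.array([r.items_a1.total() for r in eligible_1wk], dtype=float)
    labels = sk.reference_labels(eligible_1wk, sk.ReferenceStandard("LMP"))
    cfg = sk.CARTConfig(max_depth=2, min_split=50, min_leaf=25)
    tree = sk.fit_cart({"birthweight": bw, "score": score}, labels, cfg)
    assert tree.split_var == "birthweight"
    leaves = tree.leaves()
    assert len(leaves) == 4
    risks = [leaf.p_preterm for leaf in leaves]
    assert max(risks) == risks[0]  # low-bw, low-score group
    assert min(risks) == risks[-1]  # high-bw, high-score group
    assert tree.left.p_preterm > tree.right.p_preterm


class TestExtractCutoffs:
    def test_root_leaf_gives_empty(self):
        tree = sk.fit_cart({"score": np.arange(30.0)}, np.zeros(30, dtype=bool))
        assert sk.extract_cutoffs(tree) == {}

    def test_integer_score_snapping(self):
        tree = CARTNode(n=10, p_preterm=0.5, split_var="score", split_threshold=12.5,
                        left=CARTNode(n=5, p_preterm=1.0), right=CARTNode(n=5, p_preterm=0.0))
        assert sk.extract_cutoffs(tree) == {"score": [13.0]}

    def test_continuous_birthweight_not_snapped(self):
        tree = CARTNode(n=10, p_preterm=0.5, split_var="birthweight",
                        split_threshold=2.575,
                        left=CARTNode(n=5, p_preterm=1.0), right=CARTNode(n=5, p_preterm=0.0))
        assert sk.extract_cutoffs(tree) == {"birthweight": [2.575]}


def test_config_validation():
    with pytest.raises(ValueError):
        sk.CARTConfig(impurity="entropy")
    with pytest.raises(ValueError):
        sk.CARTConfig(min_leaf=0)
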