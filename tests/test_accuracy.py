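"""Two-by-two summaries, likelihood-ratio identities, ROC/AUC and MH pooling."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import sgaskit as sk
from sgaskit.accuracy import two_by_two_from_rates


def _record(ga_lmp, ga_usg, base):
    return dataclasses.replace(base, ga_lmp=ga_lmp, ga_usg=ga_usg)


class TestReferenceLabels:
    @pytest.fixture()
    def base(self, cohort_10k):
        return cohort_10k[0]

    def test_disjunction_and_conjunction(self, base):
        rec = [_record(37.5, 36.5, base)]
        assert sk.reference_labels(rec, sk.ReferenceStandard("LMP_OR_USG"))[0]
        assert not sk.reference_labels(rec, sk.ReferenceStandard("LMP_AND_USG"))[0]

    def test_strict_inequality_at_threshold(self, base):
        rec = [_record(36.9, 38.0, base), _record(37.0, 38.0, base)]
        labels = sk.reference_labels(rec, sk.ReferenceStandard("LMP"))
        assert labels.tolist() == [True, False]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            sk.ReferenceStandard("BOTH")


class TestDiagnosticSummary:
    def test_published_style_table_consistency(self):
        """Counts implied by prevalence 6.83% / Se 43.27% / Sp 90.07% at
        n = 8,591 reproduce the companion PPV, NPV and likelihood ratios."""
        t = two_by_two_from_rates(8591, 6.83, 43.27, 90.07)
        assert (t.tp, t.fp, t.fn, t.tn) == (254, 795, 333, 7209)
        s = sk.diagnostic_summary(t)
        assert s.sensitivity.value == pytest.approx(43.27, abs=0.005)
        assert s.specificity.value == pytest.approx(90.07, abs=0.005)
        assert s.ppv.value == pytest.approx(24.21, abs=0.005)
        assert s.npv.value == pytest.approx(95.58, abs=0.005)
        assert s.lr_pos.value == pytest.approx(4.36, abs=0.005)
        assert s.lr_neg.value == pytest.approx(0.63, abs=0.005)

    def test_perfect_test_flags_infinite_lr(self):
        s = sk.diagnostic_summary(sk.TwoByTwo(10, 0, 0, 90))
        assert s.sensitivity.value == 100.0 and s.specificity.value == 100.0
        assert s.lr_pos.value == float("inf") and s.lr_pos.flag == "infinite"

    def test_uninformative_test(self):
        s = sk.diagnostic_summary(sk.TwoByTwo(5, 5, 5, 5))
        assert s.sensitivity.value == 50.0 and s.specificity.value == 50.0
        assert s.lr_pos.value == pytest.approx(1.0)

    def test_bayes_consistency_ppv(self):
        """PPV from (prevalence, Se, Sp) equals PPV from counts, exactly."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = sk.TwoByTwo(*(int(v) for v in rng.integers(1, 500, size=4)))
            s = sk.diagnostic_summary(t)
            prev, se, sp = (
                s.prevalence.value / 100,
                s.sensitivity.value / 100,
                s.specificity.value / 100,
            )
            ppv_bayes = 100 * prev * se / (prev * se + (1 - prev) * (1 - sp))
            assert s.ppv.value == pytest.approx(ppv_bayes, abs=1e-9)
            # LR identities on the same summary
            assert s.lr_pos.value == pytest.approx(se / (1 - sp))
            assert s.lr_neg.value == pytest.approx((1 - se) / sp)

    def test_clopper_pearson_option(self):
        t = sk.TwoByTwo(8, 2, 3, 50)
        wilson = sk.diagnostic_summary(t)
        exact = sk.diagnostic_summary(t, ci_method="clopper-pearson")
        assert wilson.sensitivity.value == exact.sensitivity.value
        assert exact.sensitivity.ci_low <= wilson.sensitivity.ci_low

    def test_single_class_margin_rejected(self):
        with pytest.raises(ValueError):
            sk.diagnostic_summary(sk.TwoByTwo(0, 5, 0, 5))


class TestRocAuc:
    def test_perfect_separation(self):
        est = sk.roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert est.value == 1.0

    def test_constant_marker_all_ties(self):
        est = sk.roc_auc([5, 5, 5, 5], [1, 0, 1, 0])
        assert est.value == 0.5

    def test_enumerated_concordance(self):
        # pairs (0.9 vs 0.2), (0.9 vs 0.4), (0.3 vs 0.2), (0.3 vs 0.4): 3/4
        est = sk.roc_auc([0.9, 0.2, 0.3, 0.4], [1, 0, 1, 0])
        assert est.value == pytest.approx(0.75)

    def test_orientation_flip(self):
        est = sk.roc_auc([17, 16, 9, 8], [0, 0, 1, 1], lower_is_positive=True)
        assert est.value == 1.0

    def test_complement_identity_tie_free(self):
        rng = np.random.default_rng(5)
        x = rng.permutation(30).astype(float)  # tie-free
        y = rng.integers(0, 2, size=30)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        a1 = sk.roc_auc(x, y).value
        a2 = sk.roc_auc(-x, y).value
        assert a1 + a2 == pytest.approx(1.0)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(10, 100)
            x = rng.normal(size=n).round(1)  # rounding forces some ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            assert sk.roc_auc(x, y).value == pytest.approx(roc_auc_score(y, x))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sk.roc_auc([1, 2, 3], [1, 1, 1])


class TestMantelHaenszel:
    def test_single_balanced_stratum(self):
        res = sk.mantel_haenszel([sk.TwoByTwo(10, 10, 10, 10)])
        assert res.pooled_or == pytest.approx(1.0)

    def test_single_stratum_equals_crude_or(self):
        res = sk.mantel_haenszel([sk.TwoByTwo(20, 10, 5, 40)])
        assert res.pooled_or == pytest.approx(16.0)
        assert res.ci_low < 16.0 < res.ci_high

    def test_two_identical_strata_homogeneous(self):
        t = sk.TwoByTwo(20, 10, 5, 40)
        res = sk.mantel_haenszel([t, t])
        assert res.pooled_or == pytest.approx(16.0)
        assert res.breslow_day_pvalue == pytest.approx(1.0, abs=1e-6)

    def test_zero_cell_flagged_and_corrected(self):
        res = sk.mantel_haenszel([sk.TwoByTwo(5, 0, 3, 12), sk.TwoByTwo(4, 2, 3, 10)])
        assert res.corrected_strata == (0,)
        assert np.isfinite(res.pooled_or)


def test_bonferroni_alpha():
    assert sk.bonferroni_alpha(0.05, 8) == pytest.approx(0.00625)
    with pytest.raises(ValueError):
        sk.bonferroni_alpha(0.05, 0)


def test_stratified_lr_stable_without_stratum_effect(eligible_1wk):
    """With no facility effect in the generator, stratum LR+ scatters around
    the pooled LR+ only within sampling noise."""
    totals = np.array([r.items_a1.total() for r in eligible_1wk])
    labels = sk.reference_labels(eligible_1wk, sk.ReferenceStandard("LMP"))
    facilities = np.array([r.facility for r in eligible_1wk])
    pooled = sk.diagnostic_summary(sk.two_by_two(totals < 13, labels)).lr_pos
    for fac in np.unique(facilities):
        m = facilities == fac
        s = sk.diagnostic_summary(sk.two_by_two(totals[m] < 13, labels[m]))
        # stratum CI overlaps the pooled interval
        assert s.lr_pos.ci_low < pooled.ci_high and pooled.ci_low < s.lr_pos.ci_high
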