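"""ROC metrics: Mann-Whitney AUC, DeLong comparison, operating points."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from mced_cascade import (delong_test, empirical_auc, roc_summary,
                          sens_spec_at, threshold_at_specificity)


def _brute_force_auc(pos, neg):
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestEmpiricalAUC:
    def test_four_pair_hand_count(self):
        # pairs (2,1)=1 (2,2)=.5 (3,1)=1 (3,2)=1 -> 3.5/4
        assert empirical_auc([2, 3], [1, 2]) == pytest.approx(0.875)

    def test_identical_lists_give_half(self):
        assert empirical_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert empirical_auc([5, 6], [1, 2, 3]) == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=50),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=50),
    )
    def test_matches_all_pairs_brute_force(self, pos, neg):
        # integer scores force plenty of ties
        assert empirical_auc(pos, neg) == pytest.approx(
            _brute_force_auc(pos, neg), abs=1e-12)

    # scores rounded to 3 decimals so exp() stays strictly increasing in
    # floating point (denormal-scale gaps would collapse under exp)
    _scores = st.lists(
        st.floats(-3, 3, allow_nan=False).map(lambda v: round(v, 3)),
        min_size=1, max_size=30)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(pos=_scores, neg=_scores)
    def test_complement_symmetry_and_transform_invariance(self, pos, neg):
        a = empirical_auc(pos, neg)
        assert a + empirical_auc(neg, pos) == pytest.approx(1.0, abs=1e-12)
        # strictly increasing transform leaves ranks, hence AUC, unchanged
        assert empirical_auc(np.exp(pos), np.exp(neg)) == pytest.approx(a, abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(0)
        y = rng.random(200) < 0.4
        s = rng.standard_normal(200) + y
        assert empirical_auc(s[y], s[~y]) == pytest.approx(
            roc_auc_score(y, s), abs=1e-12)


class TestROCSummary:
    def test_sensitivity_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        y = rng.random(150) < 0.5
        s = rng.standard_normal(150) + 0.8 * y
        roc = roc_summary(s, y)
        assert (np.diff(roc.sensitivities) <= 1e-12).all()
        assert roc.auc == pytest.approx(empirical_auc(s[y], s[~y]))


class TestDeLong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(2)
        y = rng.random(60) < 0.5
        s = rng.standard_normal(60) + y
        res = delong_test(s, s, y)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        y = rng.random(80) < 0.5
        a = rng.standard_normal(80) + 1.2 * y
        b = rng.standard_normal(80) + 0.4 * y
        ab = delong_test(a, b, y)
        ba = delong_test(b, a, y)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_detects_large_auc_gap(self):
        rng = np.random.default_rng(4)
        y = rng.random(400) < 0.5
        strong = rng.standard_normal(400) + 2.0 * y
        weak = rng.standard_normal(400) + 0.3 * y
        res = delong_test(strong, weak, y)
        assert res.p < 0.001

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [2, 1], [True, True])


class TestSensSpecAt:
    def test_perfect_classifier(self):
        out = sens_spec_at([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert out["sensitivity"] == 1.0 and out["specificity"] == 1.0

    def test_hand_counted_half(self):
        out = sens_spec_at([0.6, 0.4, 0.3, 0.7], [1, 1, 0, 0], 0.5)
        assert out["sensitivity"] == pytest.approx(0.5)
        assert out["specificity"] == pytest.approx(0.5)

    def test_clopper_pearson_zero_successes_lower_bound(self):
        out = sens_spec_at([0.1, 0.2, 0.9], [1, 1, 0], 0.5)
        assert out["sensitivity"] == 0.0
        assert out["sensitivity_ci"][0] == 0.0

    def test_boundary_convention_is_inclusive(self):
        # score exactly at the cutoff counts positive, like the classifiers
        out = sens_spec_at([0.5, 0.5], [True, False], 0.5)
        assert out["sensitivity"] == 1.0   # cancer at cutoff detected
        assert out["specificity"] == 0.0   # noncancer at cutoff called positive


class TestThresholdAtSpecificity:
    def test_interpolated_upper_percentile(self):
        neg = np.arange(1, 101, dtype=float)
        # type-7 percentile oracle: 1 + 0.98 * 99
        assert threshold_at_specificity(neg, 0.98) == pytest.approx(98.02)

    def test_zero_target_gives_minimum(self):
        assert threshold_at_specificity([3.0, 1.0, 2.0], 0.0) == 1.0

    def test_median_target(self):
        assert threshold_at_specificity([1.0, 2.0, 3.0], 0.5) == 2.0

    def test_insufficient_negatives_rejected(self):
        with pytest.raises(ValueError):
            threshold_at_specificity(np.arange(10, dtype=float), 0.98)
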