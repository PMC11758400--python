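"""CRS: weighted score arithmetic, simplex grid search, percentile calibration."""

import numpy as np
import pytest

from mced_cascade import (CRSWeights, calibrate_crs, classify_crs,
                          empirical_auc, grid_search_leaderboard,
                          grid_search_weights, load_crs_model, raw_crs,
                          save_crs_model, score_crs, weight_lattice)


class TestRawCRS:
    def test_projection_weight_selects_feature(self):
        w = CRSWeights(1, 0, 0, 0, 0)
        assert raw_crs(w, [3.2, -1.0, 9.9, 0.1, 0.7]) == pytest.approx(3.2)

    def test_equal_weights_average_ones(self):
        w = CRSWeights(0.2, 0.2, 0.2, 0.2, 0.2)
        assert raw_crs(w, np.ones(5)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        w = CRSWeights(0.1, 0.4, 0.3, 0.1, 0.1)
        assert raw_crs(w, [1, 2, 0, -1, 0.5]) == pytest.approx(0.85)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            raw_crs(CRSWeights(1, 0, 0, 0, 0), [np.nan, 0, 0, 0, 0])

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            CRSWeights(0.5, 0.5, 0.5, 0, 0)
        with pytest.raises(ValueError):
            CRSWeights(-0.2, 0.4, 0.4, 0.2, 0.2)


class TestWeightLattice:
    def test_step_half_has_fifteen_tuples(self):
        lat = weight_lattice(0.5)
        assert lat.shape == (15, 5)  # compositions of 2 into 5 parts

    def test_lattice_is_simplex_and_lex_sorted(self):
        lat = weight_lattice(0.25)
        assert np.all(lat >= 0)
        np.testing.assert_allclose(lat.sum(axis=1), 1.0)
        as_tuples = [tuple(r) for r in lat]
        assert as_tuples == sorted(as_tuples)

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            weight_lattice(0.3)


def _brute_force_best(X, y, step):
    """Oracle: exhaustive lattice enumeration with all-pairs AUC."""
    def pair_auc(scores):
        pos, neg = scores[y], scores[~y]
        total = 0.0
        for p in pos:
            for q in neg:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
        return total / (len(pos) * len(neg))

    best_w, best_auc = None, -1.0
    for w in weight_lattice(step):
        auc = pair_auc(X @ w)
        if auc > best_auc + 1e-12:
            best_w, best_auc = w, auc
    return best_w, best_auc


class TestGridSearch:
    def test_dominant_feature_takes_all_weight(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.arange(n) < n // 2
        X = rng.standard_normal((n, 5))
        X[:, 2] = np.where(y, 10.0, 0.0)  # perfect feature
        w = grid_search_weights(X, y, step=0.25)
        scores = X @ w.as_array()
        assert empirical_auc(scores[y], scores[~y]) == pytest.approx(1.0)
        # the perfect feature must carry weight (ties resolve to the
        # lexicographically smallest tuple, not the purest projection)
        assert w.c > 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for trial in range(3):
            n = 30
            y = np.arange(n) < 14
            X = rng.standard_normal((n, 5)) + 0.8 * y[:, None] * rng.random(5)
            w = grid_search_weights(X, y, step=0.25)
            oracle_w, oracle_auc = _brute_force_best(X, y, 0.25)
            scores = X @ w.as_array()
            achieved = empirical_auc(scores[y], scores[~y])
            assert achieved == pytest.approx(oracle_auc, abs=1e-12)

    def test_duplicated_feature_matches_single_feature_auc(self):
        rng = np.random.default_rng(1)
        n = 40
        y = np.arange(n) < 20
        sig = rng.standard_normal(n) + 1.5 * y
        X = np.column_stack([sig, sig, rng.standard_normal((n, 3)).T[0],
                             rng.standard_normal(n), rng.standard_normal(n)])
        w = grid_search_weights(X, y, step=0.25)
        scores = X @ w.as_array()
        single = empirical_auc(sig[y], sig[~y])
        achieved = empirical_auc(scores[y], scores[~y])
        assert achieved >= single - 1e-12

    def test_tiny_table_matches_hand_enumeration(self):
        # 6 subjects, step 0.5: small enough to enumerate by the oracle
        X = np.array([
            [2.0, 0.1, 0.0, 1.0, 0.2],
            [1.5, 0.2, 1.0, 0.0, 0.1],
            [1.8, 0.0, 0.5, 0.5, 0.9],
            [0.2, 1.9, 0.4, 0.3, 0.8],
            [0.1, 1.5, 0.6, 0.2, 0.0],
            [0.3, 1.8, 0.2, 0.9, 0.4],
        ])
        y = np.array([True, True, True, False, False, False])
        w = grid_search_weights(X, y, step=0.5)
        oracle_w, oracle_auc = _brute_force_best(X, y, 0.5)
        scores = X @ w.as_array()
        assert empirical_auc(scores[y], scores[~y]) == pytest.approx(oracle_auc)
        np.testing.assert_allclose(w.as_array(), oracle_w)

    def test_leaderboard_sorted_and_sized(self):
        rng = np.random.default_rng(2)
        y = np.arange(30) < 15
        X = rng.standard_normal((30, 5)) + y[:, None]
        board = grid_search_leaderboard(X, y, step=0.25, top=10)
        assert len(board) == 10
        assert (np.diff(board["auc"].to_numpy()) <= 1e-12).all()

    def test_degenerate_labels_rejected(self):
        X = np.zeros((4, 5))
        with pytest.raises(ValueError):
            grid_search_weights(X, np.ones(4, dtype=bool))


class TestCalibration:
    def test_uniform_grid_maps_anchors_exactly(self):
        raw = np.arange(100) / 100.0  # 0.00 .. 0.99
        cal = calibrate_crs(raw)
        mapped = cal.apply(raw)
        assert np.quantile(mapped, 0.98) == pytest.approx(2.0, abs=1e-12)
        assert np.quantile(mapped, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_already_calibrated_scores_give_identity(self):
        rng = np.random.default_rng(3)
        raw = rng.standard_normal(500)
        cal = calibrate_crs(raw)
        cal2 = calibrate_crs(cal.apply(raw))
        assert cal2.scale == pytest.approx(1.0, abs=1e-9)
        assert cal2.offset == pytest.approx(0.0, abs=1e-9)

    def test_training_noncancer_positive_fraction_bounded(self, fitted):
        y, crs = fitted["y"], fitted["crs"]
        frac = (crs[~y] >= 2.0).mean()
        assert frac <= 0.02 + 1.0 / (~y).sum()

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            calibrate_crs(np.ones(100))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            calibrate_crs(np.arange(20, dtype=float))


class TestClassify:
    @pytest.mark.parametrize("crs,call", [
        (2.0, "positive"),       # inclusive boundary
        (1.999, "negative"),
        (-5.0, "negative"),
        (10.0, "positive"),
    ])
    def test_boundary(self, crs, call):
        assert classify_crs(crs) == call


class TestFittedCRS:
    def test_integrated_beats_best_single_feature(self, fitted):
        y, crs, rec = fitted["y"], fitted["crs"], fitted["records"]
        crs_auc = empirical_auc(crs[y], crs[~y])
        best_single = max(
            empirical_auc(rec.loc[y, f], rec.loc[~y, f])
            for f in ("cna", "fs", "endmotif", "virus"))
        poc = fitted["poc"]
        best_single = max(best_single, empirical_auc(poc[y], poc[~y]))
        # the simplex lattice contains every pure projection
        assert crs_auc >= best_single - 0.01

    def test_serialization_round_trip(self, fitted, tmp_path):
        path = tmp_path / "crs.json"
        save_crs_model(fitted["crs_model"], path)
        back = load_crs_model(path)
        np.testing.assert_allclose(
            score_crs(back, fitted["records"], fitted["poc"]), fitted["crs"])
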