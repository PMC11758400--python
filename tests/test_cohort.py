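"""Synthetic cohort generator: calibration map, sampling, and file round trips."""

import numpy as np
import pandas as pd
import pytest

from mced_cascade import (COHORT_COLUMNS, MARKERS, GENOMIC_FEATURES, STAGES,
                          UPPER_REFERENCE_LIMITS, CohortParseError, CohortSpec,
                          binormal_shift, empirical_auc, generate_cohort,
                          read_cohort, write_cohort)


class TestBinormalShift:
    def test_no_separation_at_half(self):
        assert binormal_shift(0.5) == 0.0

    @pytest.mark.parametrize("auc,expected", [
        # sqrt(2) * Phi^-1(auc), frozen from the inverse-normal oracle
        (0.877, 1.6406572725137816),
        (0.654, 0.5602299177897275),
    ])
    def test_matches_inverse_normal_oracle(self, auc, expected):
        assert binormal_shift(auc) == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_auc_recovery(self):
        # 10^6 simulated pairs: unit-variance Gaussians separated by the
        # shift should reproduce the target AUC to sampling accuracy
        delta = binormal_shift(0.654)
        rng = np.random.default_rng(0)
        pos = rng.standard_normal(10**6) + delta
        neg = rng.standard_normal(10**6)
        assert empirical_auc(pos, neg) == pytest.approx(0.654, abs=0.001)

    @pytest.mark.parametrize("bad", [0.49, -0.1, 1.0, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            binormal_shift(bad)


class TestGenerateCohort:
    def test_default_cohort_size_and_schema(self, default_cohort):
        assert len(default_cohort) == 1197
        assert list(default_cohort.columns) == list(COHORT_COLUMNS)
        assert (default_cohort["group"] == "cancer").sum() == 617
        assert (default_cohort["group"] == "noncancer").sum() == 580

    def test_seed_determinism(self):
        spec = CohortSpec(n_cancer=40, n_noncancer=40)
        a = generate_cohort(spec, seed=7)
        b = generate_cohort(spec, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(spec, seed=8)
        assert not a[list(MARKERS)].equals(c[list(MARKERS)])

    def test_noncancer_has_no_stage_and_positive_markers(self, default_cohort):
        nc = default_cohort[default_cohort["group"] == "noncancer"]
        assert (nc["stage"] == "").all()
        ca = default_cohort[default_cohort["group"] == "cancer"]
        assert ca["stage"].isin(STAGES).all()
        assert (default_cohort[list(MARKERS)] > 0).all().all()

    def test_null_feature_targets_give_null_aucs(self):
        # targets at 0.5 -> empirical AUC within MC sampling error of 0.5
        spec = CohortSpec(feature_auc_targets={f: 0.5 for f in GENOMIC_FEATURES})
        rec = generate_cohort(spec, seed=3)
        y = (rec["group"] == "cancer").to_numpy()
        for f in GENOMIC_FEATURES:
            auc = empirical_auc(rec.loc[y, f], rec.loc[~y, f])
            assert 0.45 < auc < 0.55

    def test_stage_mix_matches_probabilities(self):
        spec = CohortSpec(n_cancer=10_000, n_noncancer=1)
        rec = generate_cohort(spec, seed=5)
        stages = rec.loc[rec["group"] == "cancer", "stage"]
        for st, p in CohortSpec().stage_probs.items():
            assert (stages == st).mean() == pytest.approx(p, abs=0.02)

    def test_ptm_positivity_rises_with_stage(self):
        # marker positivity (any marker above its upper reference limit)
        # must be non-decreasing over stages I..IV
        spec = CohortSpec(n_cancer=10_000, n_noncancer=1)
        rec = generate_cohort(spec, seed=11)
        ca = rec[rec["group"] == "cancer"]
        positive = np.zeros(len(ca), dtype=bool)
        for m in MARKERS:
            positive |= (ca[m] > UPPER_REFERENCE_LIMITS[m]).to_numpy()
        rates = [positive[(ca["stage"] == st).to_numpy()].mean()
                 for st in ("I", "II", "III", "IV")]
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:])), rates

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cancer=0).validate()
        with pytest.raises(ValueError):
            CohortSpec(stage_probs={"I": 1.0}).validate()
        bad_probs = dict(CohortSpec().stage_probs)
        bad_probs["I"] += 0.1
        with pytest.raises(ValueError):
            CohortSpec(stage_probs=bad_probs).validate()
        with pytest.raises(ValueError):
            CohortSpec(feature_auc_targets={"cna": 1.2, "fs": 0.8,
                                            "endmotif": 0.8, "virus": 0.6}).validate()


class TestCohortIO:
    def test_round_trip_identity(self, default_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(default_cohort, path)
        back = read_cohort(path)
        assert len(back) == len(default_cohort)
        assert list(back.columns) == list(COHORT_COLUMNS)
        for col in ("id", "group", "stage", "sex"):
            assert (back[col].astype(str) == default_cohort[col].astype(str)).all()
        for col in ("age",) + MARKERS + GENOMIC_FEATURES:
            # equality at the file's 6-significant-digit precision
            np.testing.assert_allclose(back[col], default_cohort[col], rtol=1e-5)

    def test_empty_cohort_round_trip(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_cohort(pd.DataFrame(columns=list(COHORT_COLUMNS)), path)
        back = read_cohort(path)
        assert len(back) == 0
        assert list(back.columns) == list(COHORT_COLUMNS)

    def test_missing_column_is_schema_error(self, default_cohort, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort(default_cohort, path)
        df = pd.read_csv(path)
        df.drop(columns=["cyfra211"]).to_csv(tmp_path / "dropped.csv", index=False)
        with pytest.raises(CohortParseError, match="cyfra211"):
            read_cohort(tmp_path / "dropped.csv")

    def test_non_numeric_cell_names_row_and_column(self, default_cohort, tmp_path):
        path = tmp_path / "bad.csv"
        df = default_cohort.head(5).copy()
        df["ca125"] = df["ca125"].astype(object)
        df.loc[df.index[2], "ca125"] = "oops"
        write_cohort(df, path)
        with pytest.raises(CohortParseError, match=r"row 2.*'ca125'"):
            read_cohort(path)
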