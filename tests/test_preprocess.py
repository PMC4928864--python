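"""QC gating, detection filtering, replicates, and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirlung.data_model import Cohort, CtMatrix, SampleTable, WellQC
from mirlung.preprocess import (
    QCThresholds,
    apply_well_qc,
    collapse_replicates,
    detection_filter,
    quantile_normalize_to_mean,
    rank_normalize,
    replicate_concordance,
)
from .conftest import make_cohort


class TestWellQC:
    def _ct(self):
        return CtMatrix(["A", "B"], ["S1", "S2"],
                        [[20.0, 21.0], [22.0, 23.0]])

    @pytest.mark.parametrize("amp,cq,kept", [
        (1.30, 0.85, True),    # both gates pass
        (1.24, 0.85, False),   # amp exactly at threshold fails (strict >)
        (1.30, 0.80, False),   # cq exactly at threshold fails
        (1.20, 0.85, False),
    ])
    def test_gate_strictness(self, amp, cq, kept):
        out = apply_well_qc(self._ct(), [WellQC("A", "S1", amp, cq)])
        assert np.isfinite(out.values[0, 0]) == kept
        # untouched cells unchanged
        assert out.values[1, 1] == 23.0

    def test_no_qc_rows_is_identity(self):
        ct = self._ct()
        out = apply_well_qc(ct, [])
        np.testing.assert_array_equal(out.values, ct.values)

    def test_unknown_cell_skipped_with_warning(self, caplog):
        out = apply_well_qc(self._ct(), [WellQC("Z", "S1", 1.0, 0.1)])
        assert np.isfinite(out.values).all()


class TestDetectionFilter:
    def _ct_with_fractions(self):
        # fractions over 50 samples: 1.00, 0.80, 0.74, 0.50
        n = 50
        values = np.full((4, n), 25.0)
        values[1, :10] = np.nan
        values[2, :13] = np.nan
        values[3, :25] = np.nan
        return CtMatrix(["a", "b", "c", "d"], [f"s{i}" for i in range(n)], values)

    def test_threshold_counts(self):
        filtered, report = detection_filter(
            self._ct_with_fractions(), QCThresholds(detection_fraction=0.75))
        assert filtered.feature_ids == ["a", "b"]
        assert report["detection_fraction"].tolist() == [1.0, 0.8, 0.74, 0.5]
        assert report["kept"].tolist() == [True, True, False, False]

    def test_low_threshold_keeps_all(self):
        filtered, _ = detection_filter(
            self._ct_with_fractions(), QCThresholds(detection_fraction=0.5))
        assert filtered.n_features == 4

    def test_all_dropped_is_error(self):
        ct = CtMatrix(["a"], ["s1", "s2"], [[np.nan, 20.0]])
        with pytest.raises(ValueError, match="every feature"):
            detection_filter(ct, QCThresholds(detection_fraction=0.9))

    def test_retained_set_monotone_in_threshold(self):
        ct = self._ct_with_fractions()
        kept_sets = []
        for f in (0.4, 0.6, 0.75, 0.9, 1.0):
            filtered, _ = detection_filter(ct, QCThresholds(detection_fraction=f))
            kept_sets.append(set(filtered.feature_ids))
        for lo, hi in zip(kept_sets[1:], kept_sets):
            assert lo <= hi

    def test_subjects_denominator_counts_subjects(self):
        # 3 subjects, one profiled twice; feature detected in the replicate only
        values = np.array([[np.nan, 25.0, np.nan, np.nan]])
        ct = CtMatrix(["a"], ["s1", "s1b", "s2", "s3"], values)
        samples = SampleTable(pd.DataFrame({
            "sample_id": ["s1", "s1b", "s2", "s3"],
            "subject_id": ["p1", "p1", "p2", "p3"],
            "sex": ["male"] * 4, "fev1_fvc": [80.0] * 4}))
        _, report = detection_filter(
            ct, QCThresholds(detection_fraction=0.01,
                             detection_denominator="subjects"), samples)
        assert report["detection_fraction"].iloc[0] == pytest.approx(1 / 3)


class TestCollapseReplicates:
    def _cohort(self):
        values = np.array([[24.0, 26.0, 20.0], [np.nan, 30.0, 21.0]])
        return make_cohort(values, [80.0, 80.0, 75.0],
                           subject_ids=["p1", "p1", "p2"])

    def test_mean_per_subject(self):
        out = collapse_replicates(self._cohort(), "mean_per_subject")
        assert out.ct.n_samples == 2
        assert out.ct.values[0, 0] == pytest.approx(25.0)

    def test_missing_replicate_uses_available(self):
        out = collapse_replicates(self._cohort(), "mean_per_subject")
        assert out.ct.values[1, 0] == pytest.approx(30.0)

    def test_keep_all_is_identity(self):
        cohort = self._cohort()
        assert collapse_replicates(cohort, "keep_all") is cohort

    def test_commutes_with_feature_subsetting(self):
        cohort = self._cohort()
        a = collapse_replicates(cohort, "mean_per_subject").ct.subset_features(
            ["miR-001"])
        b = collapse_replicates(
            Cohort(cohort.ct.subset_features(["miR-001"]), cohort.samples),
            "mean_per_subject").ct
        np.testing.assert_array_equal(a.values, b.values)


class TestReplicateConcordance:
    def _cohort(self, col_b):
        values = np.column_stack([[1.0, 2.0, 3.0, 4.0], col_b])
        return make_cohort(values, [80.0, 80.0], subject_ids=["p1", "p1"])

    @pytest.mark.parametrize("col_b,rho", [
        ([1.0, 2.0, 3.0, 4.0], 1.0),          # identical profiles
        ([10.0, 8.0, 6.0, 4.0], -1.0),        # strictly decreasing transform
        ([1.0, 2.0, 4.0, 3.0], 0.8),          # hand Spearman on n=4
    ])
    def test_pair_correlations(self, col_b, rho):
        out = replicate_concordance(self._cohort(col_b))
        assert len(out) == 1
        assert out["spearman"].iloc[0] == pytest.approx(rho)

    def test_too_few_shared_features_is_missing(self):
        values = np.array([[1.0, 2.0], [np.nan, 3.0], [4.0, np.nan], [5.0, 6.0]])
        out = replicate_concordance(
            make_cohort(values, [80.0, 80.0], subject_ids=["p1", "p1"]))
        assert np.isnan(out["spearman"].iloc[0])

    def test_no_replicates_is_error(self):
        with pytest.raises(ValueError, match="two or more"):
            replicate_concordance(make_cohort([[1.0, 2.0]], [80.0, 75.0]))


class TestQuantileNormalize:
    def test_hand_oracle_two_columns(self):
        ct = CtMatrix(["a", "b", "c"], ["s1", "s2"],
                      np.array([[1.0, 6.0], [2.0, 2.0], [3.0, 4.0]]))
        out = quantile_normalize_to_mean(ct)
        # column order statistics both become the mean of sorted columns
        np.testing.assert_allclose(np.sort(out.values[:, 0]), [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.values[:, 0], [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [4.5, 1.5, 3.0])

    def test_identical_columns_fixed_point(self):
        values = np.tile(np.array([[20.0], [25.0], [30.0]]), (1, 4))
        ct = CtMatrix(["a", "b", "c"], list("wxyz"), values)
        out = quantile_normalize_to_mean(ct)
        np.testing.assert_allclose(out.values, values)

    def test_single_column_unchanged(self):
        ct = CtMatrix(["a", "b"], ["s1"], np.array([[20.0], [30.0]]))
        out = quantile_normalize_to_mean(ct)
        np.testing.assert_allclose(out.values, ct.values)

    def test_missing_cells_stay_missing_and_ranks_preserved(self, rng):
        values = rng.uniform(10, 40, size=(10, 5))
        values[rng.random(values.shape) < 0.2] = np.nan
        ct = CtMatrix([f"f{i}" for i in range(10)], list("abcde"), values)
        out = quantile_normalize_to_mean(ct)
        np.testing.assert_array_equal(np.isnan(out.values), np.isnan(values))
        for j in range(5):
            mask = np.isfinite(values[:, j])
            if mask.sum() >= 2:
                rho = stats.spearmanr(values[mask, j], out.values[mask, j]).statistic
                assert rho == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12), st.integers(2, 8))
    def test_idempotent_with_shared_order_stats(self, seed, n_feat, n_samp):
        rng = np.random.default_rng(seed)
        values = rng.uniform(5, 40, size=(n_feat, n_samp))
        ct = CtMatrix([f"f{i}" for i in range(n_feat)],
                      [f"s{j}" for j in range(n_samp)], values)
        once = quantile_normalize_to_mean(ct)
        twice = quantile_normalize_to_mean(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)
        # all complete columns share the same multiset of values
        ref = np.sort(once.values[:, 0])
        for j in range(1, n_samp):
            np.testing.assert_allclose(np.sort(once.values[:, j]), ref)
        # within-sample ordering preserved
        for j in range(n_samp):
            rho = stats.spearmanr(values[:, j], once.values[:, j]).statistic
            assert rho == pytest.approx(1.0)


class TestRankNormalize:
    def test_average_ties(self):
        np.testing.assert_allclose(
            rank_normalize([10.0, 20.0, 20.0, 40.0]), [1.0, 2.5, 2.5, 4.0])

    def test_strictly_increasing_gives_identity_ranks(self):
        np.testing.assert_allclose(rank_normalize([3.0, 5.0, 9.0]), [1, 2, 3])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, size=20)
        np.testing.assert_allclose(rank_normalize(x), rank_normalize(np.exp(x)))

    def test_missing_preserved_and_all_missing_errors(self):
        out = rank_normalize([1.0, np.nan, 2.0])
        assert np.isnan(out[1]) and out[0] == 1.0
        with pytest.raises(ValueError, match="missing"):
            rank_normalize([np.nan, np.nan])
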