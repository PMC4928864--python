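"""Per-feature OLS, CI-exclusion significance, adjustment, strata, fetal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlung.association import (
    associate_all,
    bh_adjust,
    fetal_age_association,
    fit_feature,
    fit_multivariable,
    significant_by_ci,
    stratify_by_sex,
)
from mirlung.data_model import CtMatrix, FetalSampleTable
from .conftest import make_cohort


def ols_oracle(x, y, alpha=0.05):
    """Textbook closed-form simple OLS, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    b1 = ((x - xb) * (y - yb)).sum() / sxx
    b0 = yb - b1 * xb
    resid = y - b0 - b1 * x
    s2 = (resid ** 2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    tstat = b1 / se if se > 0 else np.inf
    p = 2 * stats.t.sf(abs(tstat), n - 2)
    return b1, b0, se, (b1 - tcrit * se, b1 + tcrit * se), p


class TestFitFeature:
    def test_exact_fit_recovers_slope(self):
        res = fit_feature([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.b1 == pytest.approx(2.0)
        assert res.significant and res.usable
        assert res.ci_low == pytest.approx(2.0) and res.ci_high == pytest.approx(2.0)

    def test_matches_closed_form_oracle(self):
        x = np.arange(1.0, 7.0)
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1, 11.9])
        b1, b0, se, (lo, hi), p = ols_oracle(x, y)
        res = fit_feature(x, y)
        assert res.b1 == pytest.approx(b1, abs=1e-10)
        assert res.b0 == pytest.approx(b0, abs=1e-10)
        assert res.ci_low == pytest.approx(lo, abs=1e-10)
        assert res.ci_high == pytest.approx(hi, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_pairwise_deletion(self):
        res = fit_feature([1.0, np.nan, 3.0, 4.0, 5.0],
                          [2.0, 9.0, 6.0, np.nan, 10.0])
        assert res.n_used == 3

    def test_constant_ct_flagged_unusable(self):
        res = fit_feature([5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.usable and "constant" in res.reason
        assert not res.significant

    def test_too_few_cases_flagged_unusable(self):
        res = fit_feature([1.0, 2.0], [3.0, 4.0])
        assert not res.usable and "complete cases" in res.reason


class TestSignificantByCI:
    @pytest.mark.parametrize("lo,hi,expected", [
        (0.38, 3.59, True),    # positive interval excluding zero
        (0.56, 1.91, True),
        (-1.0, 1.0, False),    # straddles zero
        (0.0, 2.0, False),     # endpoint at zero counts as containing it
        (-2.0, 0.0, False),
        (-3.0, -0.5, True),    # negative interval
    ])
    def test_rule(self, lo, hi, expected):
        assert significant_by_ci(lo, hi) is expected

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            significant_by_ci(1.0, 0.0)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_cap_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_storey_qvalues_bounded_and_ordered(self, rng):
        p = np.concatenate([rng.uniform(0, 0.01, 10), rng.uniform(size=90)])
        q = bh_adjust(p, method="storey")
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestAssociateAll:
    def test_single_feature_bh_identity(self):
        cohort = make_cohort([[1.0, 2.0, 3.0, 4.0, 5.0]],
                             [2.0, 3.9, 6.1, 8.0, 9.9])
        results = associate_all(cohort, "fev1_fvc")
        assert results[0].p_adjusted == pytest.approx(results[0].p_value)

    def test_all_noise_calibration(self, rng):
        m, n = 60, 50
        cohort = make_cohort(24 + rng.standard_normal((m, n)),
                             78 + 8 * rng.standard_normal(n))
        results = associate_all(cohort, "fev1_fvc")
        n_sig = sum(r.significant for r in results)
        # binomial(60, 0.05) central 99.9% region
        assert n_sig <= 12

    def test_deterministic_feature_order(self, small_cohort):
        results = associate_all(small_cohort, "fev1_fvc")
        ids = [r.feature_id for r in results]
        assert ids == sorted(ids)


class TestMultivariable:
    def test_constant_covariates_reduce_to_simple_fit(self, rng):
        n = 24
        x = 24 + rng.standard_normal(n)
        y = 78 + 1.5 * (x - 24) + rng.standard_normal(n)
        cohort = make_cohort(x[None, :], y, sex=["male"] * n)
        df = cohort.samples.frame
        df["age"] = 9.0
        df["height"] = 130.0
        multi = fit_multivariable(cohort, "fev1_fvc", covariates=("age",))[0]
        simple = fit_feature(x, y)
        # constant covariates drop out; the fit reduces to the simple model
        assert multi.usable
        assert multi.b1 == pytest.approx(simple.b1, abs=1e-10)
        assert multi.ci_low == pytest.approx(simple.ci_low, abs=1e-10)

    def test_zero_noise_exact_recovery(self):
        n = 8
        rng = np.random.default_rng(5)
        x = rng.uniform(20, 28, n)
        age = rng.uniform(6, 12, n)
        height = rng.uniform(110, 160, n)
        sex = ["male", "female"] * (n // 2)
        female = np.array([s == "female" for s in sex], float)
        y = 10 + 2.0 * x - 0.5 * age + 0.1 * height + 3.0 * female
        cohort = make_cohort(x[None, :], y, sex=sex)
        cohort.samples.frame["age"] = age
        cohort.samples.frame["height"] = height
        res = fit_multivariable(cohort, "fev1_fvc")[0]
        assert res.b1 == pytest.approx(2.0, abs=1e-8)
        assert res.significant

    def test_normal_equations_oracle(self, rng):
        n = 40
        x = 24 + rng.standard_normal(n)
        age = 9 + 2 * rng.standard_normal(n)
        height = 80 + 6 * age + 5 * rng.standard_normal(n)
        sex = ["male" if v < 0.5 else "female" for v in rng.uniform(size=n)]
        female = np.array([s == "female" for s in sex], float)
        y = 70 + 1.2 * x + 0.3 * age + 0.05 * height + rng.standard_normal(n)
        cohort = make_cohort(x[None, :], y, sex=sex)
        cohort.samples.frame["age"] = age
        cohort.samples.frame["height"] = height
        X = np.column_stack([np.ones(n), x, age, female, height])
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (n - X.shape[1])
        se1 = np.sqrt(s2 * XtX_inv[1, 1])
        res = fit_multivariable(cohort, "fev1_fvc",
                                covariates=("age", "sex", "height"))[0]
        assert res.b1 == pytest.approx(beta[1], abs=1e-8)
        tcrit = stats.t.ppf(0.975, n - X.shape[1])
        assert res.ci_low == pytest.approx(beta[1] - tcrit * se1, abs=1e-8)
        assert res.ci_high == pytest.approx(beta[1] + tcrit * se1, abs=1e-8)

    def test_zero_covariate_effect_matches_simple_b1(self, rng):
        n = 80
        x = 24 + rng.standard_normal(n)
        y = 78 + 1.0 * (x - 24) + rng.standard_normal(n)
        age = 9 + 2 * rng.standard_normal(n)     # independent of y
        height = 130 + 10 * rng.standard_normal(n)
        sex = ["male" if v < 0.5 else "female" for v in rng.uniform(size=n)]
        cohort = make_cohort(x[None, :], y, sex=sex)
        cohort.samples.frame["age"] = age
        cohort.samples.frame["height"] = height
        simple = fit_feature(x, y)
        multi = fit_multivariable(cohort, "fev1_fvc")[0]
        assert multi.b1 == pytest.approx(simple.b1, abs=0.15)


class TestStratifyBySex:
    def test_classes(self, rng):
        n = 60
        sex = ["male"] * (n // 2) + ["female"] * (n // 2)
        male = np.array([s == "male" for s in sex])
        x = 24 + rng.standard_normal((3, n))
        y = 78 + 2 * rng.standard_normal(n)
        # strong male-only effect on feature 0, both-sex effect on feature 1
        y_eff = y.copy()
        x[0, male] = 24 + (y[male] - 78) * 0.8 + 0.1 * rng.standard_normal(male.sum())
        x[1] = 24 + (y - 78) * 0.8 + 0.1 * rng.standard_normal(n)
        cohort = make_cohort(x, y_eff, sex=sex)
        calls = {c.feature_id: c for c in stratify_by_sex(
            cohort, ["miR-000", "miR-001", "miR-002"])}
        assert calls["miR-000"].call_class == "male_only"
        assert calls["miR-001"].call_class == "both"
        assert calls["miR-002"].call_class == "neither"

    def test_small_stratum_unusable(self):
        cohort = make_cohort([[1.0, 2.0, 3.0, 4.0, 5.0]],
                             [2.0, 4.0, 6.0, 8.0, 10.0],
                             sex=["male"] * 4 + ["female"])
        calls = stratify_by_sex(cohort, ["miR-000"])
        assert not calls[0].female_significant


class TestFetal:
    def _fetal(self, values, ages):
        n = len(ages)
        ct = CtMatrix([f"miR-{i}" for i in range(values.shape[0])],
                      [f"F{j}" for j in range(n)], values)
        table = FetalSampleTable(pd.DataFrame(
            {"sample_id": ct.sample_ids, "gestational_age": ages}))
        return ct, table

    def test_exact_linear_trend_significant(self):
        ages = np.array([70.0, 80.0, 90.0, 100.0, 110.0])
        values = 30 - 0.05 * (ages - 90)
        ct, table = self._fetal(values[None, :], ages)
        res = fetal_age_association(ct, table)[0]
        assert res.significant
        assert res.p_value < 1e-10

    def test_noise_calibration(self, rng):
        n, m = 30, 200
        ages = rng.uniform(67, 115, n)
        values = 25 + rng.standard_normal((m, n))
        ct, table = self._fetal(values, ages)
        results = fetal_age_association(ct, table)
        frac = np.mean([r.significant for r in results])
        # 99.9% binomial bound around 0.05
        assert frac < 0.12

    def test_feature_subset_respected(self, rng):
        ages = rng.uniform(67, 115, 10)
        values = 25 + rng.standard_normal((4, 10))
        ct, table = self._fetal(values, ages)
        results = fetal_age_association(ct, table, features=["miR-1", "miR-3"])
        assert [r.feature_id for r in results] == ["miR-1", "miR-3"]
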