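import numpy as np
import pandas as pd
import pytest

from qtcohort import (
    IntervalTable,
    adjusted_rr_difference,
    distribution_diagnostics,
    fisher_exact_outliers,
    fit_multivariate,
    implied_qt_difference,
    student_t_compare,
)

from conftest import make_table


class TestStudentT:
    def test_identical_groups(self):
        r = student_t_compare([1, 2, 3], [1, 2, 3])
        assert r.t_stat == 0.0
        assert r.pvalue == 1.0

    def test_hand_computed_example(self):
        # pooled SD = 1, se = sqrt(2/3), t = -3/se
        r = student_t_compare([1, 2, 3], [4, 5, 6])
        assert r.t_stat == pytest.approx(-3.6742346, abs=1e-6)
        assert r.df == 4
        assert r.pvalue == pytest.approx(0.0213116, abs=1e-6)
        assert r.mean_difference == pytest.approx(-3.0)

    def test_t_grows_with_separation(self, rng):
        a = rng.normal(0, 1, 100)
        t1 = abs(student_t_compare(a, a + 1).t_stat)
        t2 = abs(student_t_compare(a, a + 2).t_stat)
        assert t2 > t1

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            student_t_compare([1], [2, 3])


class TestFisherExact:
    def test_reconstructed_male_outlier_table(self):
        """275/42,673 vs 36/8,631; independent R oracle gives p = 0.0119419."""
        p = fisher_exact_outliers(275, 42673, 36, 8631)
        assert p == pytest.approx(0.0119419, abs=1e-6)

    def test_reconstructed_female_outlier_table(self):
        assert fisher_exact_outliers(145, 30081, 9, 1898) == pytest.approx(1.0)

    def test_equal_rates_give_p_one(self):
        assert fisher_exact_outliers(5, 100, 5, 100) == 1.0

    def test_symmetric_under_group_swap(self):
        a = fisher_exact_outliers(17, 500, 4, 300)
        b = fisher_exact_outliers(4, 300, 17, 500)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_outliers(10, 5, 1, 100)


def constructed_log_table(rng, n=400, noise=0.0) -> IntervalTable:
    """ln QT built exactly from known coefficients (single intercept)."""
    rr = rng.uniform(0.6, 1.4, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.uniform(20, 80, n)
    manu = np.where(rng.random(n) < 0.5, "FD", "NK")
    logqt = (-1.2 + 0.347 * np.log(rr) - 0.0123 * (sex == "male")
             + 0.000686 * age + 0.0275 * (manu == "NK")
             + rng.normal(0, noise, n))
    return IntervalTable(pd.DataFrame({
        "qt": np.exp(logqt), "rr": rr, "sex": sex, "age": age,
        "manufacturer": manu,
    }))


class TestMultivariate:
    def test_zero_noise_exact_recovery(self, rng):
        fit = fit_multivariate(constructed_log_table(rng), scale="log",
                               manufacturer_order=["FD", "NK"])
        assert fit.rr.estimate == pytest.approx(0.347, abs=1e-10)
        assert fit.gender_male.estimate == pytest.approx(-0.0123, abs=1e-10)
        assert fit.age.estimate == pytest.approx(0.000686, abs=1e-10)
        assert fit.manufacturer.estimate == pytest.approx(0.0275, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_cis_contain_estimates_with_noise(self, rng):
        fit = fit_multivariate(constructed_log_table(rng, noise=0.02),
                               scale="log")
        for c in (fit.rr, fit.gender_male, fit.age, fit.manufacturer):
            assert c.ci_low <= c.estimate <= c.ci_high

    def test_single_level_factor_named(self):
        table = make_table([0.4] * 12, np.linspace(0.8, 1.1, 12),
                           sex=["male"] * 12, manufacturer=["FD", "NK"] * 6)
        with pytest.raises(ValueError, match="sex"):
            fit_multivariate(table)

    def test_raw_scale_reports_ms(self, rng):
        n = 500
        rr = rng.uniform(0.6, 1.4, n)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        age = rng.uniform(20, 80, n)
        manu = np.where(rng.random(n) < 0.5, "FD", "NK")
        qt = (0.24 + 0.153 * rr - 0.005154 * (sex == "male")
              + 0.000276 * age + 0.010610 * (manu == "NK"))
        table = IntervalTable(pd.DataFrame({
            "qt": qt, "rr": rr, "sex": sex, "age": age, "manufacturer": manu}))
        fit = fit_multivariate(table, scale="raw", manufacturer_order=["FD", "NK"])
        assert fit.rr.estimate == pytest.approx(0.153, abs=1e-10)
        assert fit.gender_male.estimate == pytest.approx(-5.154, abs=1e-8)
        assert fit.manufacturer.estimate == pytest.approx(10.610, abs=1e-8)


class TestImpliedDifference:
    def test_zero_coefficient(self):
        assert implied_qt_difference(0.0, 400.0) == 0.0

    def test_published_coefficient_back_transform(self):
        # closed form 400*(e^0.0275 - 1)
        assert implied_qt_difference(0.0275, 400.0) == pytest.approx(11.1526, abs=1e-3)

    def test_doubling(self):
        assert implied_qt_difference(np.log(2.0), 400.0) == pytest.approx(400.0)

    def test_multiplicative_consistency(self):
        b = 400.0
        up = b + implied_qt_difference(0.31, b)
        back = up + implied_qt_difference(-0.31, up)
        assert back == pytest.approx(b, rel=1e-12)


class TestAdjustedRRDifference:
    def test_noise_free_offset_recovered(self, rng):
        n = 300
        age = rng.uniform(20, 80, n)
        manu = np.array(["FD", "NK"] * (n // 2))
        rr = 0.860 + 0.08495 * (manu == "NK")
        table = IntervalTable(pd.DataFrame({
            "qt": np.full(n, 0.4), "rr": rr, "sex": "male", "age": age,
            "manufacturer": manu}))
        off = adjusted_rr_difference(table, "male", manufacturer_order=["FD", "NK"])
        assert off.coefficient_ms == pytest.approx(84.95, abs=1e-8)
        assert off.percent == pytest.approx(100 * 84.95 / 860.0, abs=1e-6)

    def test_zero_offset(self, rng):
        n = 200
        table = IntervalTable(pd.DataFrame({
            "qt": 0.4, "rr": np.full(n, 0.9), "sex": "female",
            "age": rng.uniform(20, 80, n),
            "manufacturer": ["FD", "NK"] * (n // 2)}))
        off = adjusted_rr_difference(table, "female")
        assert off.coefficient_ms == pytest.approx(0.0, abs=1e-9)
        assert off.percent == pytest.approx(0.0, abs=1e-9)

    def test_generator_means_without_age_effect(self):
        from qtcohort.simulate import CohortParams, StratumSpec, generate_cohort
        strata = (
            StratumSpec("FD", "male", 4000, 859.7, 132.8, 46.1, 9.2, 378.6, 25.7),
            StratumSpec("NK", "male", 4000, 947.6, 151.2, 49.9, 15.3, 404.0, 28.4),
        )
        params = CohortParams("raw", strata, slope=0.153, target_r2=0.6)
        table = generate_cohort(params, seed=9)
        off = adjusted_rr_difference(table, "male")
        assert off.coefficient_ms == pytest.approx(947.6 - 859.7, abs=10.0)

    def test_single_manufacturer_stratum_rejected(self):
        table = make_table([0.4] * 20, [0.9] * 20)
        with pytest.raises(ValueError, match="single-manufacturer"):
            adjusted_rr_difference(table, "male")


class TestDistributionDiagnostics:
    def test_lognormal_logs_are_closer_to_normal(self, rng):
        n = 10_000
        table = make_table(
            qt=np.exp(rng.normal(-0.9, 0.3, n)),
            rr=np.exp(rng.normal(-0.05, 0.3, n)),
        )
        diag = distribution_diagnostics(table)
        assert abs(diag.loc["log_qt", "skewness"]) < abs(diag.loc["qt", "skewness"])
        assert bool(diag.loc["log_qt", "closer_to_normal"])
        assert bool(diag.loc["log_rr", "closer_to_normal"])

    def test_normal_sample_has_small_skewness(self, rng):
        table = make_table(
            qt=rng.normal(0.4, 0.02, 10_000), rr=rng.normal(0.9, 0.1, 10_000))
        diag = distribution_diagnostics(table)
        assert abs(diag.loc["qt", "skewness"]) < 0.1
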