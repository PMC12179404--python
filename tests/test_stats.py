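"""Group tests, ANCOVA, effect sizes, correlations, RANSAC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from glymphkit.stats import (
    ancova,
    bonferroni,
    cohens_d,
    correlate,
    d_to_r,
    group_compare,
    ransac_fit,
)


def _cohort(n_per=40, shift=(0.0, 0.0, 0.0), age_effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, mu in zip(("HC", "mild", "severe"), shift):
        age = rng.normal(50 + (10 if g == "severe" else 0), 8, n_per)
        y = mu + age_effect * (age - 50) + rng.normal(0, 1, n_per)
        for a, v, s, e in zip(age, y, rng.choice(["M", "F"], n_per), rng.normal(9, 3, n_per)):
            rows.append({"group": g, "age": a, "sex": s, "education": e, "y": v})
    return pd.DataFrame(rows)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "d,r",
        [(1.147, 0.498), (2.120, 0.727), (0.578, 0.277), (0.391, 0.192), (0.0, 0.0)],
    )
    def test_d_to_r_reference_pairs(self, d, r):
        # printed d values are themselves rounded, so agreement is to
        # one unit in the last printed digit of r
        assert abs(d_to_r(d) - r) < 1e-3

    @given(st.floats(-10, 10))
    @settings(max_examples=100, deadline=None)
    def test_d_to_r_odd_increasing_bounded(self, d):
        r = d_to_r(d)
        assert -1 < r < 1
        assert np.isclose(d_to_r(-d), -r)
        assert d_to_r(d + 0.1) > r

    def test_cohens_d_pooled(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 4.0, 5.0, 6.0])
        assert np.isclose(cohens_d(x, y), -2.0 / np.std(np.r_[x - 2.5, y - 4.5], ddof=1) * 0 - cohens_d(y, x))
        # hand value: pooled sd = sqrt(5/3) on each sample -> 1.29099
        assert np.isclose(cohens_d(y, x), 2.0 / 1.2909944487358056)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_bonferroni(self):
        assert np.isclose(bonferroni(0.02, 3), 0.06)
        assert bonferroni(0.5, 3) == 1.0
        assert bonferroni(0.01, 3) >= 0.01


class TestGroupCompare:
    def test_identical_groups_null(self):
        df = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0] * 3, "group": ["HC"] * 3 + ["mild"] * 3 + ["severe"] * 3}
        )
        res = group_compare(df, "y", kind="anova")
        assert res.statistic < 1e-12 and res.p_raw > 0.999

    def test_chi2_perfect_association_hand_value(self):
        df = pd.DataFrame({"hyp": [1] * 10 + [0] * 10, "group": ["a"] * 10 + ["b"] * 10})
        res = group_compare(df, "hyp", group="group", kind="chi2")
        assert np.isclose(res.statistic, 20.0)

    def test_tukey_pairs_present(self):
        df = _cohort(shift=(0.0, 0.0, 2.0))
        res = group_compare(df, "y", kind="anova")
        assert len(res.extra["pairwise"]) == 3
        sev = [p for p in res.extra["pairwise"] if "severe" in (p["group1"], p["group2"])]
        assert all(p["p_adjusted"] < 0.01 for p in sev)

    def test_rejection_rate_matches_power_oracle(self):
        """1-sd shift at n=50/group: empirical two-group rejection rate
        within a binomial band of the analytic noncentral-F power."""
        from scipy import stats as sps

        n, reps, shift = 50, 400, 1.0
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(reps):
            a = rng.normal(0, 1, n)
            b = rng.normal(shift, 1, n)
            rejections += sps.f_oneway(a, b)[1] < 0.05
        nc = n * shift**2 / 2.0
        crit = sps.f.ppf(0.95, 1, 2 * n - 2)
        power = sps.ncf.sf(crit, 1, 2 * n - 2, nc)
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rejections / reps - power) < 4 * se + 0.01


class TestAncova:
    def test_null_covariates_match_anova(self):
        df = _cohort(shift=(0.0, 0.5, 1.0), seed=3)
        res_anova = group_compare(df, "y", kind="anova")
        # covariates present but with zero true effect: F should be close
        res_ancova = ancova(df, "y", covariates=("education",))
        assert np.isclose(res_ancova.statistic, res_anova.statistic, rtol=0.15)

    def test_confounded_difference_vanishes_after_adjustment(self):
        # group difference entirely through age
        df = _cohort(shift=(0.0, 0.0, 0.0), age_effect=0.3, seed=5)
        raw = group_compare(df, "y", kind="anova")
        adj = ancova(df, "y", covariates=("age",))
        assert raw.p_raw < 0.01  # severe group is older, so unadjusted differs
        assert adj.p_raw > 0.05

    def test_rank_ancova_monotone_invariance(self):
        df = _cohort(shift=(0.0, 0.5, 1.0), seed=7)
        r1 = ancova(df, "y", ranked=True)
        df2 = df.assign(y=np.exp(df["y"]))
        r2 = ancova(df2, "y", ranked=True)
        assert np.isclose(r1.statistic, r2.statistic, atol=1e-10)

    def test_pairwise_bonferroni_never_below_raw(self):
        df = _cohort(shift=(0.0, 0.8, 1.5), seed=1)
        res = ancova(df, "y")
        for pair in res.extra["pairwise"]:
            assert pair["p_bonferroni"] >= pair["p_raw"]
        assert len(res.extra["pairwise"]) == 3

    def test_second_factor_main_effect(self):
        df = _cohort(shift=(0.0, 0.0, 0.0), seed=11)
        df["hypertension"] = np.random.default_rng(0).choice([0, 1], len(df))
        res = ancova(df, "y", second_factor="hypertension")
        assert "second_factor" in res.extra
        assert res.extra["second_factor"]["p"] > 0.01  # no planted effect

    def test_collinear_covariates_rejected(self):
        df = _cohort(seed=2)
        df["age2"] = df["age"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            ancova(df, "y", covariates=("age", "age2"))

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        reps, hits = 400, 0
        for i in range(reps):
            df = _cohort(n_per=40, seed=1000 + i)
            res = ancova(df, "y")
            hits += res.p_raw < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x + 1)
        assert np.isclose(r, 1.0)

    def test_monotone_nonlinearity(self):
        x = np.linspace(-2, 2, 50)
        rho, _ = correlate(x, x**3, method="spearman")
        r, _ = correlate(x, x**3, method="pearson")
        assert np.isclose(rho, 1.0) and r < 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate(np.ones(10), np.arange(10.0))

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(500):
            x = rng.normal(0, 1, 76)
            y = 0.4 * x + np.sqrt(1 - 0.16) * rng.normal(0, 1, 76)
            rs.append(correlate(x, y)[0])
        assert abs(np.mean(rs) - 0.4) < 0.03


class TestRansac:
    def test_clean_data_matches_ols(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (80, 2))
        y = 1.5 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(0, 0.1, 80)
        fit = ransac_fit(X, y, residual_threshold=1.0, seed=0)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coefficients, ols.params[1:], atol=0.02)
        assert fit.n_inliers == 80

    def test_outliers_rejected_slope_recovered(self):
        rng = np.random.default_rng(1)
        n = 100
        x = rng.uniform(-2, 2, n)
        y = 2.0 * x + rng.normal(0, 0.2, n)
        out = rng.choice(n, 20, replace=False)
        y[out] += rng.choice([-1, 1], 20) * rng.uniform(5, 10, 20)
        fit = ransac_fit(x[:, None], y, seed=3)
        assert abs(fit.coefficients[0] - 2.0) / 2.0 < 0.05
        assert fit.n_inliers < n

    def test_controls_residualized_out(self):
        rng = np.random.default_rng(2)
        n = 200
        age = rng.normal(50, 10, n)
        x = 0.5 * age + rng.normal(0, 1, n)
        y = 0.8 * age + rng.normal(0, 1, n)  # y depends on age only
        fit = ransac_fit(x[:, None], y, controls=age[:, None], residual_threshold=5.0, seed=0)
        assert abs(fit.coefficients[0]) < 0.1

    def test_refit_on_inliers_reproduces_coefficients(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 60)
        y = 1.2 * x + rng.normal(0, 0.3, 60)
        y[:6] += 8.0
        fit = ransac_fit(x[:, None], y, seed=1)
        refit = sm.OLS(y[fit.inlier_mask], sm.add_constant(x[fit.inlier_mask])).fit()
        assert np.isclose(refit.params[1], fit.coefficients[0], atol=1e-8)

    def test_null_predictor_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        covered = 0
        for i in range(100):
            x = rng.normal(0, 1, 60)
            y = rng.normal(0, 1, 60)
            fit = ransac_fit(x[:, None], y, residual_threshold=3.0, seed=i)
            refit = sm.OLS(y[fit.inlier_mask], sm.add_constant(x[fit.inlier_mask])).fit()
            lo, hi = refit.conf_int()[1]
            covered += lo <= 0 <= hi
        assert covered >= 90

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 1, 50)
        a = ransac_fit(x[:, None], y, seed=42)
        b = ransac_fit(x[:, None], y, seed=42)
        assert np.array_equal(a.inlier_mask, b.inlier_mask)
        assert np.allclose(a.coefficients, b.coefficients)
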