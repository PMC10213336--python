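import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from symptomnet import (
    ContingencyTable,
    ancova_group_effect,
    fit_logistic,
    pearson_chi2,
    pooled_t_test,
    pooled_t_test_raw,
    prevalence_wald_ci,
    wilcoxon_rank_sum,
)

from oracles import logistic_ml_oracle, wilcoxon_exact_p


class TestPrevalence:
    def test_study_headline_interval(self):
        p, lo, hi = prevalence_wald_ci(357, 1101)
        assert (round(100 * p, 1), round(100 * lo, 1), round(100 * hi, 1)) == (
            32.4, 29.7, 35.2,
        )

    def test_zero_successes_clipped(self):
        p, lo, hi = prevalence_wald_ci(0, 100)
        assert p == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_computed_half(self):
        p, lo, hi = prevalence_wald_ci(50, 100)
        assert (round(100 * lo, 1), round(100 * hi, 1)) == (40.2, 59.8)

    def test_wilson_option_brackets_proportion(self):
        p, lo, hi = prevalence_wald_ci(3, 10, method="wilson")
        assert lo < p < hi and 0 < lo and hi < 1

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(0.05, 0.95), st.integers(30, 2000))
    def test_width_shrinks_like_root_n(self, p, n):
        k = int(round(p * n))
        _, lo1, hi1 = prevalence_wald_ci(k, n)
        _, lo4, hi4 = prevalence_wald_ci(4 * k, 4 * n)
        if 0 < lo1 and hi1 < 1:  # unclipped interval: exact 1/sqrt(n) scaling
            assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            prevalence_wald_ci(1, 0)
        with pytest.raises(ValueError):
            prevalence_wald_ci(5, 4)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected_chi2, expected_df",
        [
            ([[152, 205], [175, 569]], 42.0, 1),        # visit difficulty
            ([[90, 248, 19], [144, 512, 88]], 14.4, 2),  # financial status
            ([[27, 135, 195], [58, 221, 465]], 7.4, 2),  # social media use
            ([[232, 125], [543, 201]], 7.4, 1),          # medication compliance
            ([[23, 334], [29, 715]], 3.5, 1),            # physical disease
        ],
    )
    def test_guardian_table_rows_reproduce(self, table, expected_chi2, expected_df):
        chi2, df, p = pearson_chi2(np.array(table))
        assert round(chi2, 1) == expected_chi2
        assert df == expected_df

    def test_proportional_rows_give_zero(self):
        chi2, df, _ = pearson_chi2(np.array([[10, 20, 30], [20, 40, 60]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_permutation_and_transpose(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 50, size=(3, 4))
        chi2, df, p = pearson_chi2(t)
        chi2p, dfp, _ = pearson_chi2(t[rng.permutation(3)][:, rng.permutation(4)])
        chi2t, dft, _ = pearson_chi2(t.T)
        assert chi2p == pytest.approx(chi2) and dfp == df
        assert chi2t == pytest.approx(chi2) and dft == df

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2(np.array([[0, 0], [5, 6]]))

    def test_crosstab_roundtrip(self):
        a = pd.Series(["x", "x", "y", "y", "y"])
        b = pd.Series([0, 1, 0, 1, 1])
        tab = ContingencyTable.crosstab(a, b)
        assert tab.counts.sum() == 5


class TestTTests:
    def test_equal_means_zero(self):
        t, df, p = pooled_t_test(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_guardian_age_row(self):
        t, df, _ = pooled_t_test(43.3, 11.4, 744, 42.5, 12.1, 357)
        assert 1.05 <= t <= 1.07  # summary inputs are rounded
        assert df == 1099

    def test_raw_matches_summary(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 40), rng.normal(0.3, 1.2, 55)
        t1, df1, p1 = pooled_t_test_raw(x, y)
        t2, df2, p2 = pooled_t_test(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert t1 == pytest.approx(t2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-10)
        assert df1 == df2

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            pooled_t_test(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            z, p = wilcoxon_rank_sum([2, 2, 2], [2, 2])
        assert z == 0.0 and p == 1.0

    def test_disjoint_supports_large_z(self):
        x = np.arange(30) + 100.0
        y = np.arange(30.0)
        z, p = wilcoxon_rank_sum(x, y)
        assert abs(z) > 6

    def test_matches_exact_permutation_small_n(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.8, 1, 8)
        y = rng.normal(0, 1, 8)
        z, p = wilcoxon_rank_sum(x, y)
        assert abs(p - wilcoxon_exact_p(x, y)) < 0.01

    def test_tie_corrected_variance_matches_mannwhitney(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 4, 60)
        y = rng.integers(0, 5, 50)
        z, p = wilcoxon_rank_sum(x, y)
        mw = stats.mannwhitneyu(x, y, use_continuity=False, method="asymptotic")
        assert p == pytest.approx(mw.pvalue, abs=1e-10)


class TestLogistic:
    def test_single_binary_predictor_equals_cross_product_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 400)
        logit = -0.5 + 1.2 * x
        y = (rng.random(400) < 1 / (1 + np.exp(-logit))).astype(int)
        res = fit_logistic(y, pd.DataFrame({"x": x}))
        a = np.sum((x == 1) & (y == 1))
        b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1))
        d = np.sum((x == 0) & (y == 0))
        assert res.odds_ratio("x") == pytest.approx(a * d / (b * c), abs=1e-8)

    def test_matches_direct_likelihood_maximization(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = (rng.random(100) < 1 / (1 + np.exp(-(0.3 + X["a"] - 0.5 * X["b"])))).astype(int)
        res = fit_logistic(y, X)
        Xc = np.column_stack([np.ones(100), X.to_numpy()])
        beta = logistic_ml_oracle(y.to_numpy(float), Xc)
        assert np.abs(res.table["coef"].to_numpy() - beta).max() < 1e-6

    def test_null_pvalues_near_nominal(self):
        """Outcome independent of predictors: ~5% of Wald p below 0.05."""
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(40):
            X = pd.DataFrame(
                rng.normal(size=(2000, 10)), columns=[f"x{i}" for i in range(10)]
            )
            y = rng.integers(0, 2, 2000)
            res = fit_logistic(y, X)
            pvals.extend(res.table["p"].iloc[1:].tolist())  # skip intercept
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= frac <= 0.08

    def test_or_ci_brackets_or(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=300)})
        y = rng.integers(0, 2, 300)
        res = fit_logistic(y, X)
        t = res.table
        assert ((t["ci_lower"] <= t["OR"]) & (t["OR"] <= t["ci_upper"])).all()
        assert np.allclose(t["OR"], np.exp(t["coef"]))

    def test_separation_flagged(self):
        x = np.concatenate([np.zeros(30), np.ones(30)])
        y = x.copy()
        with pytest.warns(RuntimeWarning, match="separation"):
            res = fit_logistic(y, pd.DataFrame({"x": x}))
        assert res.separation_warning

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(
                np.array([0, 1] * 10), pd.DataFrame({"x": np.ones(20)})
            )


class TestAncova:
    def test_no_covariates_equals_t_squared(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=200)
        g = rng.integers(0, 2, 200)
        res = ancova_group_effect(y, g, None)
        t, df, p = pooled_t_test_raw(y[g == 0], y[g == 1])
        assert res.F == pytest.approx(t**2, abs=1e-8)
        assert res.df_den == df - 0  # same residual df without covariates
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_null_permutation_pvalues_uniform(self):
        rng = np.random.default_rng(29)
        y = rng.normal(size=2000)
        cov = pd.DataFrame({"c": rng.normal(size=2000)})
        pvals = [
            ancova_group_effect(y, rng.permutation([0, 1] * 1000), cov).p
            for _ in range(200)
        ]
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= frac <= 0.09
        # Kolmogorov-Smirnov against uniform as a fuller check
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_covariate_names_alias(self):
        y = np.random.default_rng(1).normal(size=50)
        g = np.array([0, 1] * 25)
        cov = pd.DataFrame({"twin": g.astype(float)})
        with pytest.raises(ValueError, match="alias"):
            ancova_group_effect(y, g, cov)

    def test_adjusted_means_shift_with_group_effect(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 2, 500)
        c = rng.normal(size=500)
        y = 2.0 - 1.5 * g + 0.8 * c + rng.normal(size=500)
        res = ancova_group_effect(y, g, pd.DataFrame({"c": c}))
        assert res.adjusted_means["group=1"] < res.adjusted_means["group=0"]
        assert res.F > 10
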