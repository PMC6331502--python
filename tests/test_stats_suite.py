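import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxpitch.stats_suite import (bonferroni, correlation, eta_p2_from_F,
                                  fisher_z, mixed_anova, p_from_r,
                                  pooled_t_and_d, shapiro_wilk, steiger_z,
                                  tukey_outliers)


class TestPooledT:
    @pytest.mark.parametrize("m1,s1,m2,s2,t_exp,d_exp", [
        (81.64, 10.76, 51.45, 32.05, 3.573, 1.263),   # sadness rows
        (89.85, 6.71, 68.37, 27.82, 3.002, 1.061),    # fear rows
        (93.13, 5.43, 90.63, 9.11, 0.943, 0.333),     # neutral rows
    ])
    def test_group_rows_reproduce_published_statistics(self, m1, s1, m2, s2,
                                                       t_exp, d_exp):
        res = pooled_t_and_d(m1, s1, 16, m2, s2, 16)
        assert res.t == pytest.approx(t_exp, abs=0.005)
        assert res.d == pytest.approx(d_exp, abs=0.005)
        assert res.df == 30

    def test_identical_groups(self):
        res = pooled_t_and_d(50, 10, 16, 50, 10, 16)
        assert res.t == 0.0 and res.d == 0.0 and res.p == 1.0

    def test_zero_pooled_sd_with_difference_is_singular(self):
        with pytest.raises(ZeroDivisionError):
            pooled_t_and_d(60, 0, 16, 50, 0, 16)

    def test_scipy_cross_check(self):
        from scipy.stats import ttest_ind_from_stats
        mine = pooled_t_and_d(81.64, 10.76, 16, 51.45, 32.05, 16)
        ref = ttest_ind_from_stats(81.64, 10.76, 16, 51.45, 32.05, 16)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    @given(st.floats(-50, 50), st.floats(1, 30), st.floats(-50, 50),
           st.floats(1, 30), st.integers(3, 40), st.integers(3, 40))
    @settings(deadline=None, max_examples=50)
    def test_t_d_consistency_identity(self, m1, s1, m2, s2, n1, n2):
        res = pooled_t_and_d(m1, s1, n1, m2, s2, n2)
        assert res.d == pytest.approx(
            res.t * math.sqrt(1 / n1 + 1 / n2), rel=1e-9)


class TestEtaSquared:
    @pytest.mark.parametrize("F,df1,df2,expected", [
        (11.594, 1, 30, 0.279), (15.062, 5, 26, 0.743), (2.346, 5, 26, 0.311)])
    def test_published_effects(self, F, df1, df2, expected):
        assert eta_p2_from_F(F, df1, df2) == pytest.approx(expected, abs=5e-4)

    def test_zero_F(self):
        assert eta_p2_from_F(0.0, 3, 28) == 0.0

    @given(st.floats(0, 100), st.integers(1, 6), st.integers(2, 200))
    @settings(deadline=None, max_examples=50)
    def test_identity_with_F(self, F, df1, df2):
        eta = eta_p2_from_F(F, df1, df2)
        if eta < 1.0:
            assert F * df1 * (1 - eta) == pytest.approx(eta * df2, abs=1e-6)


def _manova_oracle(D, groups):
    """statsmodels MANOVA on difference scores, effect-coded group."""
    from statsmodels.multivariate.manova import MANOVA
    df = pd.DataFrame(D, columns=[f"d{i}" for i in range(D.shape[1])])
    df["g"] = groups
    lhs = "+".join(df.columns[:-1])
    res = MANOVA.from_formula(f"{lhs} ~ C(g, Sum)", data=df).mv_test()
    out = {}
    for effect, key in (("within", "Intercept"), ("interaction", "C(g, Sum)")):
        stat = res.results[key]["stat"].loc["Wilks' lambda"]
        out[effect] = (float(stat["Value"]), float(stat["F Value"]))
    return out


class TestMixedAnova:
    def test_published_design_dfs(self, rng):
        Y = rng.normal(70, 15, (32, 6))
        groups = np.array(["asd"] * 16 + ["comparison"] * 16)
        res = mixed_anova(Y, groups)
        assert (res["group"].df1, res["group"].df2) == (1, 30)
        assert (res["within"].df1, res["within"].df2) == (5, 26)
        assert (res["interaction"].df1, res["interaction"].df2) == (5, 26)

    def test_eta_identities(self, rng):
        Y = rng.normal(0, 1, (32, 6)) + np.linspace(0, 2, 6)
        groups = np.array(["a"] * 16 + ["b"] * 16)
        res = mixed_anova(Y, groups)
        for effect in ("within", "interaction"):
            r = res[effect]
            assert r.eta_p2 == pytest.approx(1 - r.wilks_lambda, abs=1e-9)
            assert r.eta_p2 == pytest.approx(
                eta_p2_from_F(r.F, r.df1, r.df2), abs=1e-9)

    def test_constant_within_levels_gives_zero_within_F(self, rng):
        subject_means = rng.normal(50, 5, 12)
        Y = np.repeat(subject_means[:, None], 4, axis=1)
        Y += rng.normal(0, 1, (12, 1))  # same shift for every level
        groups = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(np.linalg.LinAlgError):
            # zero difference-score variance is rank deficient by design
            mixed_anova(Y, groups)

    def test_two_level_case_reduces_to_difference_score_glm(self, rng):
        # with k=2 the single difference score makes the multivariate tests
        # coefficient t-tests in an effect-coded OLS fit; F must equal t^2
        import statsmodels.api as sm
        Y = rng.normal(0, 1, (12, 2)) + rng.normal(0, 1, (12, 1))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = mixed_anova(Y, groups)
        d = Y[:, 1] - Y[:, 0]
        X = np.column_stack([np.ones(12), np.repeat([1.0, -1.0], 6)])
        fit = sm.OLS(d, X).fit()
        assert res["within"].F == pytest.approx(fit.tvalues[0] ** 2, rel=1e-9)
        assert res["interaction"].F == pytest.approx(fit.tvalues[1] ** 2,
                                                     rel=1e-9)

    @pytest.mark.parametrize("n_per_group,k", [(4, 3), (3, 3)])
    def test_matches_manova_oracle_small_instances(self, n_per_group, k, rng):
        for _ in range(5):
            Y = rng.normal(0, 1, (2 * n_per_group, k)) \
                + rng.normal(0, 1, (2 * n_per_group, 1))
            groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
            res = mixed_anova(Y, groups)
            oracle = _manova_oracle(Y[:, 1:] - Y[:, :-1], groups)
            for effect in ("within", "interaction"):
                lam, F = oracle[effect]
                assert res[effect].wilks_lambda == pytest.approx(lam, abs=1e-9)
                assert res[effect].F == pytest.approx(F, abs=1e-9)

    def test_between_F_equals_t_squared(self, rng):
        Y = rng.normal(60, 12, (20, 4)) + np.repeat([0, 5], 10)[:, None]
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = mixed_anova(Y, groups)
        means = Y.mean(axis=1)
        t = pooled_t_and_d(means[:10].mean(), means[:10].std(ddof=1), 10,
                           means[10:].mean(), means[10:].std(ddof=1), 10)
        assert res["group"].F == pytest.approx(t.t ** 2, rel=1e-9)

    def test_incomplete_data_rejected(self):
        Y = np.ones((6, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError):
            mixed_anova(Y, ["a"] * 3 + ["b"] * 3)


class TestCorrelation:
    @pytest.mark.parametrize("r,n,tails,expected", [
        (-0.672, 15, 2, 0.006), (-0.489, 16, 1, 0.027), (-0.501, 16, 2, 0.048)])
    def test_published_p_values(self, r, n, tails, expected):
        direction = "negative" if tails == 1 else None
        assert p_from_r(r, n, tails, direction) == \
            pytest.approx(expected, abs=0.001)

    def test_one_tailed_wrong_direction(self):
        p2 = p_from_r(0.489, 16, 2)
        assert p_from_r(0.489, 16, 1, "negative") == \
            pytest.approx(1 - p2 / 2)

    def test_perfectly_linear(self, rng):
        x = rng.normal(size=20)
        res = correlation(x, 2 * x + 1, gate="pearson")
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_gate_selects_spearman_for_skewed_data(self, rng):
        x = rng.exponential(size=40) ** 3
        y = x + rng.normal(0, 0.1, size=40)
        res = correlation(x, y, gate="auto")
        assert res.method == "spearman"
        assert len(res.normality_gate) == 2 and min(res.normality_gate) < 0.05

    def test_gate_keeps_pearson_for_normal_data(self):
        rng = np.random.default_rng(12345)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = correlation(x, y, gate="auto")
        assert min(res.normality_gate) > 0.05  # premise: both pass the gate
        assert res.method == "pearson"

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation(np.ones(10), rng.normal(size=10))


class TestShapiroWilk:
    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])

    def test_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0, 3.0])

    def test_detects_heavy_skew(self, rng):
        x = rng.exponential(size=50)
        w, p = shapiro_wilk(x)
        assert p < 0.05 and w < 1.0


class TestTukeyOutliers:
    def test_gross_outlier_flagged(self):
        values = list(range(1, 9)) + [100]
        assert tukey_outliers(values) == [8]

    def test_uniform_spread_clean(self):
        assert tukey_outliers(np.linspace(0, 10, 20)) == []

    def test_single_inflated_jnd_flagged(self):
        # one participant with a much larger pitch JND than the rest
        jnds = [28.0, 35.5, 41.0, 47.0, 52.0, 60.0, 66.0, 72.0, 190.0]
        flagged = tukey_outliers(jnds)
        assert flagged == [8]
        assert tukey_outliers(jnds, method="haverage") == [8]


class TestFisherZ:
    def test_published_comparison(self):
        res = fisher_z(-0.554, 16, -0.346, 15)
        assert res.z == pytest.approx(-0.66, abs=0.01)
        assert res.p > 0.05

    def test_equal_correlations_null(self):
        res = fisher_z(0.4, 20, 0.4, 25)
        assert res.z == 0.0 and res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        assert fisher_z(-0.554, 16, -0.346, 15).z == \
            pytest.approx(-fisher_z(-0.346, 15, -0.554, 16).z)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0, 16, 0.3, 15)


class TestSteigerZ:
    def test_null_identity(self):
        assert steiger_z(0.5, 0.5, 0.3, 16).z == 0.0

    def test_antisymmetry(self):
        a = steiger_z(0.6, 0.3, 0.4, 30).z
        b = steiger_z(0.3, 0.6, 0.4, 30).z
        assert a == pytest.approx(-b, abs=1e-12)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(0.9, -0.9, 0.9, 30)

    def test_sign_follows_larger_correlation(self):
        assert steiger_z(0.7, 0.2, 0.3, 40).z > 0


class TestBonferroni:
    def test_six_emotions_threshold(self):
        res = bonferroni([0.001, 0.05], m=6)
        assert res["threshold"] == pytest.approx(0.05 / 6)
        assert res["significant"] == [True, False]

    def test_single_test_keeps_alpha(self):
        assert bonferroni([0.04], m=1)["significant"] == [True]

    def test_adjusted_p_capped(self):
        assert bonferroni([0.5], m=6)["adjusted_p"] == [1.0]
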