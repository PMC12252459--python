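"""Statistical engine against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from alpinetherm.stats import (
    anova_table_from_ss,
    anova_variance_partition,
    fit_smooth_model,
    mann_whitney,
    oneway_anova_lt50,
    paired_decoupling_test,
    pca_environment,
    residual_diagnostics,
    spearman,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sequential_ss_oracle(y, columns):
    """Type-I SS via nested-model RSS differences (explicit lstsq fits)."""
    n = len(y)
    x = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    out = []
    for col in columns:
        x = np.column_stack([x, col])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ beta) ** 2).sum())
        out.append(rss_prev - rss)
        rss_prev = rss
    return np.array(out), rss_prev


def mann_whitney_exact_oracle(a, b):
    """U by all-pairs counting; p by exhaustive enumeration of group splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u_stat = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    dist = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = pooled[list(idx)]
        gb = np.delete(pooled, list(idx))
        dist.append(sum((x > y) + 0.5 * (x == y) for x in ga for y in gb))
    dist = np.array(dist)
    p = min(1.0, 2.0 * min((dist <= u_stat).mean(), (dist >= u_stat).mean()))
    return u_stat, p


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 30)
        res = pca_environment(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_independent_variables_share_variance_equally(self, rng):
        data = pd.DataFrame(rng.standard_normal((20_000, 5)),
                            columns=list("abcde"))
        assert np.allclose(pca_environment(data).variance_fractions, 0.2,
                           atol=0.02)

    def test_fractions_match_eigendecomposition_oracle(self, rng):
        data = pd.DataFrame(rng.standard_normal((60, 5)) @ rng.random((5, 5)),
                            columns=list("abcde"))
        res = pca_environment(data)
        eigvals = np.sort(np.linalg.eigvalsh(np.corrcoef(data.to_numpy().T)))[::-1]
        np.testing.assert_allclose(res.variance_fractions,
                                   eigvals / eigvals.sum(), atol=1e-10)

    def test_loadings_orthonormal_and_fractions_sum_to_one(self, rng):
        data = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
        res = pca_environment(data)
        load = res.loadings.to_numpy()
        np.testing.assert_allclose(load.T @ load, np.eye(4), atol=1e-10)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_sign_convention_fixes_largest_loading_positive(self, rng):
        data = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        res = pca_environment(data)
        for comp in res.loadings.columns:
            col = res.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_environment(pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5]}))


# ---------------------------------------------------------------------------
# additive smooth model
# ---------------------------------------------------------------------------

class TestSmoothModel:
    def test_linear_signal_shrinks_to_one_edf(self, rng):
        x = rng.standard_normal((108, 2))
        y = 3.0 + 2.0 * x[:, 0]
        fit = fit_smooth_model(y, x)
        assert fit.terms.loc["x1", "edf"] == pytest.approx(1.0, abs=0.1)
        assert fit.adjusted_r2 >= 0.999

    def test_pure_noise_predictor_rarely_significant(self):
        rejections = 0
        n_reps = 60
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            x = r.standard_normal((80, 2))
            y = 1.0 + np.sin(x[:, 0]) + 0.3 * r.standard_normal(80)
            fit = fit_smooth_model(y, x, k=8)
            if fit.terms.loc["x2", "p"] <= 0.05:
                rejections += 1
        assert rejections <= 0.1 * n_reps + 2  # near-nominal type-I rate

    def test_matches_ols_on_noisy_linear_signal(self, rng):
        x = rng.standard_normal(120)
        y = 1.0 + 0.8 * x + 0.5 * rng.standard_normal(120)
        fit = fit_smooth_model(y, x[:, None])
        slope, intercept = np.polyfit(x, y, 1)
        ols_resid = y - (intercept + slope * x)
        rss_ols = float(ols_resid @ ols_resid)
        rss_gam = float(fit.residuals @ fit.residuals)
        assert rss_gam <= rss_ols * 1.001  # penalized fit nests the line
        assert fit.adjusted_r2 == pytest.approx(
            1 - (rss_ols / 118) / (np.var(y, ddof=1)), abs=0.02
        )

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_smooth_model(rng.standard_normal(10), rng.standard_normal((10, 1)))

    def test_k_exceeding_unique_values_rejected(self):
        x = np.tile(np.arange(5.0), 8)[:, None]
        with pytest.raises(ValueError, match="basis"):
            fit_smooth_model(np.arange(40.0), x, k=10)


# ---------------------------------------------------------------------------
# sequential variance partition
# ---------------------------------------------------------------------------

class TestVariancePartition:
    def test_matches_nested_rss_oracle_on_random_designs(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 25))
            data = pd.DataFrame(
                rng.standard_normal((n, 3)), columns=["PH", "CI", "PI"]
            )
            data["date"] = rng.integers(0, 2, n).astype(float)
            data["TD"] = (
                0.5 * data["PH"] - 0.8 * data["CI"] + rng.standard_normal(n)
            )
            table = anova_variance_partition(data)
            cols = [
                data["PH"], data["CI"], data["PI"],
                data["PH"] * data["CI"], data["date"],
            ]
            ss, rss = sequential_ss_oracle(data["TD"].to_numpy(),
                                           [c.to_numpy() for c in cols])
            np.testing.assert_allclose(
                table["Sum Sq"].to_numpy()[:-1], ss, rtol=1e-8, atol=1e-10
            )
            np.testing.assert_allclose(table.loc["Residuals", "Sum Sq"], rss,
                                       rtol=1e-8)

    def test_ss_conservation(self, rng):
        data = pd.DataFrame(rng.standard_normal((30, 3)),
                            columns=["PH", "CI", "PI"])
        data["date"] = 0.0
        data["TD"] = rng.standard_normal(30)
        table = anova_variance_partition(data, "TD ~ PH + CI + PI")
        total = float(((data["TD"] - data["TD"].mean()) ** 2).sum())
        assert table["Sum Sq"].sum() == pytest.approx(total, rel=1e-8)
        assert table["explained_%"].sum() == pytest.approx(100.0, rel=1e-8)

    def test_order_dependence_with_correlated_terms(self, rng):
        ph = rng.standard_normal(40)
        ci = 0.8 * ph + 0.3 * rng.standard_normal(40)
        data = pd.DataFrame({"PH": ph, "CI": ci,
                             "TD": ph + ci + rng.standard_normal(40)})
        fwd = anova_variance_partition(data, "TD ~ PH + CI")
        rev = anova_variance_partition(data, "TD ~ CI + PH")
        assert abs(fwd.loc["PH", "Sum Sq"] - rev.loc["PH", "Sum Sq"]) > 1.0

    def test_order_invariance_with_orthogonal_design(self):
        # +/-1 factorial columns are exactly orthogonal
        ph = np.tile([1.0, -1.0], 10)
        ci = np.repeat([1.0, -1.0], 10)
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"PH": ph, "CI": ci,
                             "TD": ph - ci + rng.standard_normal(20)})
        fwd = anova_variance_partition(data, "TD ~ PH + CI")
        rev = anova_variance_partition(data, "TD ~ CI + PH")
        assert fwd.loc["PH", "Sum Sq"] == pytest.approx(rev.loc["PH", "Sum Sq"],
                                                        rel=1e-8)

    def test_constant_predictor_contributes_nothing(self, rng):
        data = pd.DataFrame({"PH": rng.standard_normal(20)})
        data["PI"] = 3.0  # constant column, centered away by the intercept
        data["TD"] = data["PH"] + 0.1 * rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank"):
            anova_variance_partition(data, "TD ~ PH + PI")

    def test_replay_from_printed_ss(self):
        table = anova_table_from_ss(
            ["Height", "Circularity"], [45.02, 36.21],
            residual_ss=50.28, residual_df=21,
        )
        assert table.loc["Height", "F"] == pytest.approx(45.02 / (50.28 / 21),
                                                         rel=1e-12)
        assert table.attrs["total_ss"] == pytest.approx(131.51)


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_decoupling_test(np.array([2.0, 4.0, 6.0]),
                                     np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-10)
        assert res.df == 2
        assert res.estimate == pytest.approx(2.0)

    def test_symmetric_perturbations_give_zero_t(self):
        at = np.array([20.0, 21.0, 22.0, 23.0])
        pt = at + np.array([0.1, -0.1, 0.1, -0.1])
        assert paired_decoupling_test(pt, at).statistic == pytest.approx(0.0)

    def test_null_simulation_gives_uniform_p(self):
        pvals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            at = r.normal(20, 3, 40)
            pt = at + r.normal(0, 1, 40)
            pvals.append(paired_decoupling_test(pt, at).p_value)
        # KS against U(0,1): should not reject at the 1 % level
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_decoupling_test(np.array([1.0, 2.0, 3.0]),
                                   np.array([0.0, 1.0, 2.0]))


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0

    def test_identical_groups_midpoint_u(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n_a, n_b = rng.integers(2, 7, size=2)
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # no ties
            a, b = pooled[:n_a], pooled[n_a:]
            res = mann_whitney(a, b)
            u_oracle, p_oracle = mann_whitney_exact_oracle(a, b)
            # scipy reports U of the first sample
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestOnewayAnova:
    def test_zero_within_variance_flagged(self):
        with pytest.raises(ValueError, match="within"):
            oneway_anova_lt50([[1.0, 1.0], [2.0, 2.0]])

    def test_two_groups_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        res = oneway_anova_lt50([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p_t, rel=1e-10)
        assert res.df == (1, 25)

    def test_power_monotone_in_effect_size(self):
        power = []
        for effect in (0.0, 0.15, 0.4):
            hits = 0
            for seed in range(150):
                r = np.random.default_rng(seed)
                groups = [r.normal(effect * g, 1.0, 7) for g in range(6)]
                if oneway_anova_lt50(groups).p_value < 0.05:
                    hits += 1
            power.append(hits / 150)
        assert power[0] < power[1] < power[2]
        assert power[0] < 0.12  # near-nominal size under the null


class TestSpearman:
    def test_monotone_sequences(self):
        up = spearman([1, 2, 3, 4, 5.0], [2, 4, 8, 16, 32.0])
        down = spearman([1, 2, 3, 4, 5.0], [5, 4, 3, 2, 1.0])
        assert up.statistic == pytest.approx(1.0)
        assert down.statistic == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, 12).astype(float)  # heavy ties
            y = x + rng.integers(0, 3, 12)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            res = spearman(x, y)
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert res.statistic == pytest.approx(oracle, rel=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestDiagnostics:
    def test_gaussian_homoscedastic_residuals_pass(self):
        passes = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.standard_normal(100)
            resid = r.standard_normal(100)
            rep = residual_diagnostics(resid, exog=x)
            passes += rep.normality_ok and rep.homoscedastic_ok
        assert passes >= 85  # two 5 %-level tests jointly pass ~90 %

    def test_breusch_pagan_detects_fitted_value_heteroscedasticity(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            fitted = r.uniform(1, 5, 200)
            resid = r.standard_normal(200) * fitted
            if not residual_diagnostics(resid, fitted=fitted).homoscedastic_ok:
                hits += 1
        assert hits >= 90

    def test_shapiro_detects_heavy_tails(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            resid = r.standard_t(2, 100)
            if not residual_diagnostics(resid, exog=r.standard_normal(100)).normality_ok:
                hits += 1
        assert hits >= 80

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            residual_diagnostics(np.array([0.1, 0.2]), exog=np.array([1.0, 2.0]))
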