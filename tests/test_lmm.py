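"""REML engine: classical limits, external oracle, Satterthwaite df."""

import numpy as np
import pytest
import statsmodels.api as sm

from prespeech.errors import DesignError
from prespeech.lmm import (
    CorrPair,
    VarComp,
    fit_mixed,
    intercept_design,
    pair_design,
    slope_design,
)


def _intercept_data(rng, k=12, m=10, tau=2.0, sigma=1.0, beta=(1.0, 0.5)):
    codes = np.repeat(np.arange(k), m)
    u = rng.normal(0, tau, k)
    x = rng.normal(size=k * m)
    X = np.column_stack([np.ones(k * m), x])
    y = X @ beta + u[codes] + rng.normal(0, sigma, k * m)
    return X, y, codes, k


class TestClassicalLimits:
    def test_no_random_terms_equals_ols(self):
        rng = np.random.default_rng(1)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, 1.5] + rng.normal(0, 1, n)
        fit = fit_mixed(X, y, [])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-10)
        np.testing.assert_allclose(fit.df, n - 2)  # OLS residual df

    def test_balanced_grouped_data_without_clustering_terms_is_ols(self):
        rng = np.random.default_rng(2)
        g = np.repeat([0.0, 1.0], 30)
        X = np.column_stack([np.ones(60), g])
        y = 3.0 + 2.0 * g + rng.normal(0, 1, 60)
        fit = fit_mixed(X, y, [])
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(DesignError):
            fit_mixed(X, np.arange(20.0), [])


class TestAgainstStatsmodels:
    """statsmodels MixedLM is the independent REML oracle."""

    def test_random_intercept_estimates_match(self):
        rng = np.random.default_rng(3)
        X, y, codes, k = _intercept_data(rng)
        fit = fit_mixed(X, y, [VarComp("g", intercept_design(codes, k))])
        ref = sm.MixedLM(y, X, groups=codes).fit(reml=True)
        np.testing.assert_allclose(fit.beta, ref.fe_params, rtol=1e-4)
        np.testing.assert_allclose(
            fit.se, np.asarray(ref.bse_fe), rtol=1e-3
        )
        np.testing.assert_allclose(
            fit.variance_components["var(g)"], np.asarray(ref.cov_re)[0, 0], rtol=1e-3
        )
        np.testing.assert_allclose(
            fit.variance_components["var(residual)"], ref.scale, rtol=1e-3
        )

    def test_correlated_slope_matches(self):
        rng = np.random.default_rng(4)
        k, m = 15, 12
        codes = np.repeat(np.arange(k), m)
        x = rng.normal(size=k * m)
        cov = np.array([[4.0, 1.0], [1.0, 1.0]])
        b = rng.multivariate_normal([0, 0], cov, k)
        y = 1.0 + 0.5 * x + b[codes, 0] + b[codes, 1] * x + rng.normal(0, 1, k * m)
        X = np.column_stack([np.ones(k * m), x])
        fit = fit_mixed(X, y, [CorrPair("g", pair_design(codes, k, x))])
        ref = sm.MixedLM(y, X, groups=codes, exog_re=X).fit(reml=True)
        np.testing.assert_allclose(fit.beta, ref.fe_params, rtol=1e-3)
        np.testing.assert_allclose(fit.se, np.asarray(ref.bse_fe), rtol=5e-3)


class TestSatterthwaite:
    def test_reduces_to_residual_df_without_random_effects(self):
        rng = np.random.default_rng(5)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(0, 1, n)
        fit = fit_mixed(X, y, [])
        assert fit.satterthwaite_df(np.array([0.0, 1.0])) == n - 2

    def test_matches_welch_on_two_group_heteroscedastic_means(self):
        rng = np.random.default_rng(6)
        n1, n2 = 15, 20
        y = np.r_[rng.normal(0, 1, n1), rng.normal(1, 3, n2)]
        g = np.r_[np.zeros(n1), np.ones(n2)]
        X = np.column_stack([np.ones(n1 + n2), g])
        # extra per-observation variance for group 2 == heteroscedastic model
        Z2 = np.zeros((n1 + n2, n2))
        Z2[np.arange(n1, n1 + n2), np.arange(n2)] = 1.0
        fit = fit_mixed(X, y, [VarComp("extra", Z2)])
        s1 = y[:n1].var(ddof=1)
        s2 = y[n1:].var(ddof=1)
        welch_df = (s1 / n1 + s2 / n2) ** 2 / (
            (s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1)
        )
        got = fit.satterthwaite_df(np.array([0.0, 1.0]))
        assert got == pytest.approx(welch_df, rel=1e-3)
        assert fit.se[1] == pytest.approx(np.sqrt(s1 / n1 + s2 / n2), rel=1e-4)

    def test_balanced_one_way_intercept_df_is_clusters_minus_one(self):
        rng = np.random.default_rng(7)
        k, m = 10, 8
        codes = np.repeat(np.arange(k), m)
        y = 3.0 + rng.normal(0, 2, k)[codes] + rng.normal(0, 1, k * m)
        X = np.ones((k * m, 1))
        fit = fit_mixed(X, y, [VarComp("g", intercept_design(codes, k))])
        assert fit.satterthwaite_df(np.array([1.0])) == pytest.approx(k - 1, abs=0.1)

    def test_path_agrees_with_pointwise(self):
        rng = np.random.default_rng(8)
        X, y, codes, k = _intercept_data(rng)
        fit = fit_mixed(X, y, [VarComp("g", intercept_design(codes, k))])
        ws = np.array([0.0, 0.3, 1.0])
        c0 = np.array([0.0, 1.0])
        c1 = np.array([1.0, 0.0])
        path = fit.satterthwaite_df_path(c0, c1, ws)
        point = [fit.satterthwaite_df(c0 + w * c1) for w in ws]
        np.testing.assert_allclose(path, point, rtol=1e-6)


class TestHonestDiagnostics:
    def test_zero_cluster_variance_flags_singular(self):
        rng = np.random.default_rng(9)
        k, m = 8, 12
        codes = np.repeat(np.arange(k), m)
        y = 2.0 + rng.normal(0, 1, k * m)  # no cluster variance at all
        X = np.ones((k * m, 1))
        fit = fit_mixed(X, y, [VarComp("g", intercept_design(codes, k))])
        assert fit.singular
        assert fit.variance_components["var(g)"] < 1e-4 * np.var(y)

    def test_parameter_recovery_with_no_random_variance(self):
        rng = np.random.default_rng(10)
        n = 4000
        x = rng.normal(size=n)
        g = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), g, x, g * x])
        beta = np.array([10.0, 2.0, -1.0, 0.5])
        y = X @ beta + rng.normal(0, 1.0, n)
        codes = rng.integers(0, 6, n)
        fit = fit_mixed(
            X, y, [VarComp("sp", intercept_design(codes, 6))]
        )
        # planted random variance is zero: estimates match the truth to
        # Monte-Carlo error and the fit reports the boundary honestly
        np.testing.assert_allclose(fit.beta, beta, atol=0.12)
        assert fit.singular


class TestSimulateRefit:
    def test_round_trip_recovers_structure(self):
        rng = np.random.default_rng(11)
        X, y, codes, k = _intercept_data(rng, k=20, m=15, tau=3.0)
        fit = fit_mixed(X, y, [VarComp("g", intercept_design(codes, k))])
        sim_rng = np.random.default_rng(0)
        draws = [fit.refit(fit.simulate(sim_rng)) for _ in range(30)]
        vars_g = [d.variance_components["var(g)"] for d in draws]
        assert np.median(vars_g) == pytest.approx(
            fit.variance_components["var(g)"], rel=0.5
        )

    def test_slope_design_builder(self):
        codes = np.array([0, 0, 1, 1])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        Z = slope_design(codes, 2, x)
        np.testing.assert_array_equal(
            Z, [[1, 0], [2, 0], [0, 3], [0, 4]]
        )
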