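"""OLS prediction models, diagnostics, intervals and benchmarks."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from codcast.errors import RankDeficiencyError
from codcast.regression import (
    diagnose,
    durbin_watson,
    fit_model,
    orthogonalize_predictors,
    persistence_forecast,
    predict,
    random_chance_model,
    shuffle_design,
)
from codcast.series import AlignedDesign, align
from codcast.synthetic import simulate_upstream_index

from conftest import make_series


def toy_design(rng, n=40, p=2, coef=None, noise_sd=1.0, intercept=2.0):
    X = rng.normal(size=(n, p))
    coef = np.asarray(coef if coef is not None else rng.normal(size=p))
    y = intercept + X @ coef + rng.normal(0, noise_sd, n)
    return AlignedDesign(
        predictand="y", predictor_names=[f"x{i}" for i in range(p)],
        leads=[0] * p, years=np.arange(1950, 1950 + n), y=y, X=X,
    )


class TestFit:
    def test_noiseless_fit_is_exact(self, rng):
        d = toy_design(rng, n=30, p=1, coef=[0.5], noise_sd=0.0,
                       intercept=2.0)
        m = fit_model(d)
        assert m.intercept == pytest.approx(2.0, abs=1e-10)
        assert m.coef[0] == pytest.approx(0.5, abs=1e-10)
        assert m.resid_sd == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_and_statsmodels(self, rng):
        d = toy_design(rng, n=40, p=2)
        m = fit_model(d)
        A = d.augmented()
        beta_ne = np.linalg.solve(A.T @ A, A.T @ d.y)  # independent oracle
        assert np.allclose([m.intercept, *m.coef], beta_ne, atol=1e-8)
        sm_fit = sm.OLS(d.y, A).fit()
        assert np.allclose([m.intercept, *m.coef], sm_fit.params, atol=1e-8)
        assert m.resid_sd == pytest.approx(np.sqrt(sm_fit.mse_resid),
                                           rel=1e-8)

    def test_residuals_mean_zero_and_training_reproduction(self, rng):
        d = toy_design(rng, n=50, p=3)
        m = fit_model(d)
        assert abs(m.residuals.mean()) < 1e-10
        fc = predict(m, {
            name: make_series(d.X[:, i], name=name)
            for i, name in enumerate(d.predictor_names)
        }, target_years=d.years)
        assert np.allclose(fc.prediction, m.fitted, atol=1e-10)

    def test_rank_deficient_design_raises_with_guidance(self, rng):
        x = rng.normal(size=30)
        d = AlignedDesign("y", ["a", "b"], [0, 0],
                          np.arange(1950, 1980), rng.normal(size=30),
                          np.column_stack([x, 2 * x]))
        with pytest.raises(RankDeficiencyError, match="orthogonalize"):
            fit_model(d)

    def test_ols_optimality_against_perturbations(self, rng):
        d = toy_design(rng, n=40, p=2)
        m = fit_model(d)
        A = d.augmented()
        beta = np.array([m.intercept, *m.coef])
        mse = np.mean((d.y - A @ beta) ** 2)
        for _ in range(20):
            perturbed = beta + rng.normal(0, 0.05, size=beta.shape)
            assert mse <= np.mean((d.y - A @ perturbed) ** 2) + 1e-12

    def test_every_second_point_fit_is_consistent(self, scenario):
        # thinning the rows (removing lag-1 autocorrelation) leaves the
        # coefficients essentially unchanged for the true-lag model
        dataset, truth = scenario
        design = align(dataset["TSB"], [(dataset["FSC"], 4),
                                        (dataset["BSO"], 3),
                                        (dataset["HR"], 2)])
        full = fit_model(design)
        thin = AlignedDesign(design.predictand, design.predictor_names,
                             design.leads, design.years[::2],
                             design.y[::2], design.X[::2])
        thinned = fit_model(thin, min_extra_rows=5)
        se_full = full.resid_sd * np.sqrt(np.diag(full.xtx_inv))[1:]
        se_thin = thinned.resid_sd * np.sqrt(np.diag(thinned.xtx_inv))[1:]
        assert np.all(np.abs(thinned.coef - full.coef)
                      <= 2 * (se_full + se_thin))


class TestOrthogonalize:
    def test_duplicate_column_becomes_degenerate_zero(self, rng):
        x = rng.normal(size=30)
        d = AlignedDesign("y", ["a", "b"], [0, 0],
                          np.arange(1950, 1980), rng.normal(size=30),
                          np.column_stack([x, x]))
        od = orthogonalize_predictors(d)
        assert np.allclose(od.X[:, 1], 0.0, atol=1e-10)
        assert od.degenerate == ["b"]

    def test_idempotent_on_orthogonal_columns(self, rng):
        d = toy_design(rng, n=200, p=2)
        od = orthogonalize_predictors(d)
        od2 = orthogonalize_predictors(od)
        assert np.allclose(od.X, od2.X, atol=1e-10)

    def test_columns_mutually_uncorrelated(self, rng):
        d = toy_design(rng, n=60, p=3)
        od = orthogonalize_predictors(d)
        c = np.cov(od.X, rowvar=False)
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 1e-10

    def test_span_invariance_of_fitted_values(self, rng):
        d = toy_design(rng, n=60, p=3)
        m_raw = fit_model(d)
        m_orth = fit_model(orthogonalize_predictors(d))
        assert np.allclose(m_raw.fitted, m_orth.fitted, atol=1e-8)
        assert np.allclose(m_raw.residuals, m_orth.residuals, atol=1e-8)

    def test_orthogonalized_model_predicts_in_raw_space(self, rng):
        d = toy_design(rng, n=60, p=2)
        m = fit_model(orthogonalize_predictors(d))
        yhat = m.linear_predict(d.X)
        assert np.allclose(yhat, fit_model(d).fitted, atol=1e-8)


class TestDiagnostics:
    def test_durbin_watson_matches_statsmodels(self, rng):
        e = rng.normal(size=200)
        from statsmodels.stats.stattools import durbin_watson as sm_dw
        assert durbin_watson(e) == pytest.approx(sm_dw(e), abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.4, 0.8])
    def test_durbin_watson_closed_form(self, rho, rng):
        # DW ~ 2(1 - rho1) for AR(1) residuals
        e = simulate_upstream_index(5000, rho, 1.0, rng, name="e").values
        assert durbin_watson(e) == pytest.approx(2 * (1 - rho), abs=0.1)

    def test_white_noise_residuals_pass_all_checks(self, rng):
        d = toy_design(rng, n=500, p=2)
        report = diagnose(fit_model(d))
        assert report.independent and report.homoscedastic
        assert 1.8 < report.durbin_watson < 2.2

    def test_autocorrelated_noise_is_flagged(self, rng):
        # paper-like situation: full-series fit leaves AR(1)-ish residuals
        n = 300
        X = rng.normal(size=(n, 1))
        noise = simulate_upstream_index(n, 0.4, 1.0, rng, name="n").values
        d = AlignedDesign("y", ["x"], [0], np.arange(1950, 1950 + n),
                          0.8 * X[:, 0] + noise, X)
        report = diagnose(fit_model(d))
        assert not report.independent
        assert report.durbin_watson < 1.5
        assert report.resid_ac1 == pytest.approx(0.4, abs=0.15)


class TestPredict:
    def test_interval_matches_parametric_bootstrap(self, rng):
        # independent oracle: refit on parametric resamples of the truth,
        # add residual draws, take the 95% band of simulated outcomes
        n, sigma = 60, 0.7
        X = rng.normal(size=(n, 1))
        beta = np.array([1.0, 0.6])
        d = AlignedDesign("y", ["x"], [0], np.arange(1950, 1950 + n),
                          beta[0] + beta[1] * X[:, 0]
                          + rng.normal(0, sigma, n), X)
        m = fit_model(d)
        x0 = np.array([1.0, 1.5])
        A = d.augmented()
        cov = np.linalg.inv(A.T @ A)
        draws = 10000
        betas = rng.multivariate_normal(
            [m.intercept, *m.coef], m.resid_sd ** 2 * cov, size=draws)
        sims = betas @ x0 + rng.normal(0, m.resid_sd, draws)
        boot_half = (np.quantile(sims, 0.975)
                     - np.quantile(sims, 0.025)) / 2
        fc = predict(m, {"x": make_series(np.array([1.5, 1.5]),
                                          start_year=2020, name="x")},
                     target_years=np.array([2020]))
        assert fc.pi_half[0] == pytest.approx(boot_half, rel=0.10)

    def test_forecast_horizon_year_arithmetic(self, rng):
        # predictors through 2017 with lead 7 support forecasts to 2024
        x = make_series(rng.normal(size=68), start_year=1950, name="x")
        y = make_series(rng.normal(size=60) + 0.5 * x.values[:60],
                        start_year=1950, name="y")
        design = align(y, [(x, 7)])
        m = fit_model(design)
        fc = predict(m, {"x": x}, last_observed_year=2009)
        assert fc.years[-1] == 2024
        assert fc.future[fc.years > 2009].all()

    def test_missing_lagged_predictor_year_omitted_with_notice(self, rng):
        vals = rng.normal(size=68)
        vals[30] = np.nan  # 1980 missing -> target 1987 unavailable
        x = make_series(vals, name="x")
        y = make_series(rng.normal(size=60) + 0.5 * vals[:60], name="y")
        m = fit_model(align(y, [(x, 7)]))
        fc = predict(m, {"x": x})
        assert 1987 not in fc.years
        assert any("1987" in note for note in fc.notices)


class TestBenchmarks:
    def test_persistence_equals_explicit_construction(self, rng):
        obs = make_series(rng.normal(size=40), name="obs")
        for lag in range(1, 8):
            fc = persistence_forecast(obs, lag)
            for year, pred in zip(fc.years, fc.prediction):
                assert pred == obs.value(year - lag)

    def test_persistence_lag_one_is_one_year_shift(self, rng):
        obs = make_series(rng.normal(size=20), name="obs")
        fc = persistence_forecast(obs, 1)
        assert np.array_equal(fc.prediction, obs.values)
        assert np.array_equal(fc.years, obs.years + 1)

    def test_shuffled_columns_are_permutations(self, rng):
        d = toy_design(rng, n=40, p=2)
        sd = shuffle_design(d, rng)
        for j in range(2):
            assert np.allclose(np.sort(sd.X[:, j]), np.sort(d.X[:, j]))
        assert np.array_equal(sd.y, d.y)

    def test_random_chance_model_has_no_skill(self, rng):
        d = toy_design(rng, n=60, p=2, coef=[0.8, 0.5], noise_sd=0.3)
        rc = random_chance_model(d, seed=rng)
        r = np.corrcoef(rc.fitted, d.y)[0, 1]
        assert abs(r) < 0.45  # genuine model reaches ~0.95 here
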