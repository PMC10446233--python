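"""The penalized additive mixed model: basis, REML fit, prediction, simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from feverseek import FitConfig, gamm_engine, survey_prep
from feverseek.errors import BasisError, ConfigurationError
from feverseek.gamm_engine import (
    build_spline_basis,
    fit_gamm,
    fix_tail_trend,
    predict_frame,
    predict_rate,
    sample_coefficients,
)

YEARS = np.arange(1990, 2021)


def simulate_observations(rng, n_countries=30, years=None, country_sd=0.5,
                          region_of=None, trend=None, n_eff=600.0,
                          base_logit=0.3, sampling_noise=True):
    """National observations straight from a logit-scale additive truth."""
    years = YEARS[::3] if years is None else np.asarray(years)
    countries = [f"C{i:02d}" for i in range(n_countries)]
    if region_of is None:
        region_of = {c: f"R{i % 2}" for i, c in enumerate(countries)}
    offsets = rng.normal(0.0, country_sd, n_countries)
    rows = []
    for i, country in enumerate(countries):
        lin = base_logit + offsets[i] + (
            trend(years) if trend is not None else np.zeros(len(years))
        )
        p = expit(lin)
        if sampling_noise:
            rate = rng.binomial(int(n_eff), p) / n_eff
        else:
            rate = p
        for year, r in zip(years, rate):
            rows.append({"country": country, "year": int(year), "rate": float(r),
                         "lo95": float(r), "hi95": float(r), "n_eff": float(n_eff)})
    return pd.DataFrame(rows), region_of, offsets


class TestSplineBasis:
    def test_dimension_five_gives_four_free_columns(self):
        basis = build_spline_basis(YEARS.astype(float), 5)
        assert basis.n_columns == 4
        assert basis.degree == 3

    def test_penalty_symmetric_positive_definite(self):
        basis = build_spline_basis(YEARS.astype(float), 5)
        np.testing.assert_allclose(basis.penalty, basis.penalty.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(basis.penalty) > 0)

    def test_columns_sum_to_zero_over_fitting_inputs(self):
        basis = build_spline_basis(YEARS.astype(float), 5)
        np.testing.assert_allclose(basis.matrix(YEARS).sum(axis=0), 0.0, atol=1e-10)

    def test_constant_target_gives_zero_contribution(self):
        """Constants live in the intercept: fitting a constant through the
        constrained columns returns coefficients of zero."""
        basis = build_spline_basis(YEARS.astype(float), 5)
        B = basis.matrix(YEARS)
        X = np.column_stack([np.ones(len(YEARS)), B])
        coef, *_ = np.linalg.lstsq(X, np.full(len(YEARS), 3.7), rcond=None)
        np.testing.assert_allclose(coef[1:], 0.0, atol=1e-10)

    def test_linear_target_reproduced_without_penalty(self):
        basis = build_spline_basis(YEARS.astype(float), 5)
        target = 0.05 * (YEARS - 2005.0)
        B = basis.matrix(YEARS)
        X = np.column_stack([np.ones(len(YEARS)), B])
        coef, *_ = np.linalg.lstsq(X, target, rcond=None)
        np.testing.assert_allclose(X @ coef, target, atol=1e-10)

    def test_too_few_distinct_inputs_error(self):
        with pytest.raises(BasisError):
            build_spline_basis([1.0, 2.0, 2.0, 1.0], 5)


class TestFitGamm:
    def test_matches_dense_penalized_normal_equations_oracle(self):
        """Fixed smoothing parameters: coefficients equal an independently
        assembled dense solve of (X'WX + S) b = X'Wy to 1e-8."""
        rng = np.random.default_rng(0)
        obs, region_of, _ = simulate_observations(rng, n_countries=12)
        lam = {"trend": 5.0, "country": 2.0}
        config = FitConfig(fixed_smoothing=lam)
        fit = fit_gamm(obs, None, region_of, config)

        # independent assembly: raw B-spline matrices via scipy, dense solve
        y = np.array([survey_prep.empirical_logit(r, n)
                      for r, n in zip(obs["rate"], obs["n_eff"])])
        w = np.array([1.0 / survey_prep.logit_variance(r, n)
                      for r, n in zip(obs["rate"], obs["n_eff"])])
        p = fit.coefficients.size
        X = np.zeros((len(obs), p))
        S = np.zeros((p, p))
        for block in fit.blocks:
            if block.kind == "region_intercept":
                for region, j in fit.region_index.items():
                    X[:, block.start + j] = (obs["country"].map(region_of) == region)
            elif block.kind == "country":
                for country, j in fit.country_index.items():
                    X[:, j] = (obs["country"] == country)
                S[block.sl, block.sl] = lam["country"] * np.eye(block.size)
            elif block.kind == "trend":
                mask = (obs["country"].map(region_of) == block.region).to_numpy()
                basis = block.basis
                raw = BSpline.design_matrix(
                    obs.loc[mask, "year"].to_numpy(dtype=float),
                    basis.knots, basis.degree,
                ).toarray()
                X[np.flatnonzero(mask), block.sl] = raw @ basis.constraint
                S[block.sl, block.sl] = lam["trend"] * block.penalty
        beta = np.linalg.solve(X.T @ (w[:, None] * X) + S, X.T @ (w * y))
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_infinite_penalty_collapses_to_region_means(self):
        """Huge smoothing with no country term leaves only region intercepts,
        equal to weighted means of the empirical logits per region."""
        rng = np.random.default_rng(1)
        obs, region_of, _ = simulate_observations(rng, n_countries=10)
        config = FitConfig(include_country=False,
                           fixed_smoothing={"trend": 1e12})
        fit = fit_gamm(obs, None, region_of, config)
        y = np.array([survey_prep.empirical_logit(r, n)
                      for r, n in zip(obs["rate"], obs["n_eff"])])
        w = np.array([1.0 / survey_prep.logit_variance(r, n)
                      for r, n in zip(obs["rate"], obs["n_eff"])])
        for region, intercept in fit.region_intercepts.items():
            mask = (obs["country"].map(region_of) == region).to_numpy()
            expected = np.dot(w[mask], y[mask]) / w[mask].sum()
            assert intercept == pytest.approx(expected, abs=1e-8)

    def test_country_effect_sd_recovered(self):
        """REML recovers a 0.5-logit country random-effect sd (median of
        replicates within 0.15)."""
        rng = np.random.default_rng(2)
        estimates = []
        for _ in range(12):
            obs, region_of, _ = simulate_observations(
                rng, n_countries=30, years=YEARS[::3], country_sd=0.5
            )
            fit = fit_gamm(obs, None, region_of, FitConfig())
            estimates.append(fit.country_effect_sd)
        assert abs(np.median(estimates) - 0.5) < 0.15

    def test_reml_optimum_no_worse_than_grid(self):
        rng = np.random.default_rng(3)
        obs, region_of, _ = simulate_observations(rng, n_countries=8)
        fit = fit_gamm(obs, None, region_of, FitConfig())
        grid_scores = [score for _, score in fit.reml_trace if np.isfinite(score)]
        assert fit.reml_score <= min(grid_scores) + 1e-9

    def test_monotone_shrinkage_of_country_effects(self):
        rng = np.random.default_rng(4)
        obs, region_of, _ = simulate_observations(rng, n_countries=15)
        variances = []
        for lam in (0.1, 10.0, 1000.0, 1e6):
            fit = fit_gamm(obs, None, region_of,
                           FitConfig(fixed_smoothing={"trend": 10.0, "country": lam}))
            variances.append(np.var(list(fit.country_effects.values())))
        assert all(a >= b - 1e-12 for a, b in zip(variances, variances[1:]))

    def test_predictions_invariant_to_row_order(self):
        rng = np.random.default_rng(5)
        obs, region_of, _ = simulate_observations(rng, n_countries=6)
        fit_a = fit_gamm(obs, None, region_of, FitConfig())
        fit_b = fit_gamm(obs.sample(frac=1.0, random_state=7), None, region_of,
                         FitConfig())
        frame = pd.DataFrame({"country": ["C00", "C03"], "year": [1995, 2015]})
        np.testing.assert_allclose(
            predict_frame(fit_a, frame), predict_frame(fit_b, frame), atol=1e-8
        )

    def test_noise_free_world_recovered(self):
        """With noiseless dense observations the fit tracks truth closely."""
        rng = np.random.default_rng(6)
        trend = lambda t: 0.6 * np.sin((t - 1990) / 30 * np.pi)
        obs, region_of, offsets = simulate_observations(
            rng, n_countries=12, years=YEARS, country_sd=0.5,
            n_eff=50_000.0, trend=trend, sampling_noise=False,
        )
        fit = fit_gamm(obs, None, region_of, FitConfig())
        frame = obs[["country", "year"]]
        predicted = predict_frame(fit, frame)
        np.testing.assert_array_less(
            np.abs(predicted - obs["rate"].to_numpy()).mean(), 0.02
        )



@pytest.fixture(scope="module")
def fitted_plain():
    rng = np.random.default_rng(7)
    obs, region_of, _ = simulate_observations(rng, n_countries=6)
    return fit_gamm(obs, None, region_of, FitConfig())


@pytest.fixture(scope="module")
def fitted_trend():
    rng = np.random.default_rng(8)
    trend = lambda t: 0.5 * np.sin((t - 1990) / 10)
    obs, region_of, _ = simulate_observations(
        rng, n_countries=8, years=YEARS, trend=trend
    )
    return fit_gamm(obs, None, region_of, FitConfig())


class TestPredict:
    def test_zero_coefficients_give_half(self, fitted_plain):
        import copy

        fit = copy.deepcopy(fitted_plain)
        fit.coefficients = np.zeros_like(fit.coefficients)
        assert predict_rate(fit, "C00", 2000) == pytest.approx(0.5)

    def test_linear_predictor_clipped(self, fitted_plain):
        import copy

        fit = copy.deepcopy(fitted_plain)
        fit.coefficients = np.zeros_like(fit.coefficients)
        block = fit._block("region_intercept")
        fit.coefficients[block.start + fit.region_index[fit.region_of["C00"]]] = 50.0
        rate = predict_rate(fit, "C00", 2000)
        assert rate < 1.0
        assert rate == pytest.approx(expit(15.0))

    def test_unknown_country_errors(self, fitted_plain):
        from feverseek.errors import MissingEffectError

        with pytest.raises(MissingEffectError):
            predict_rate(fitted_plain, "NOWHERE", 2000)


class TestFixTailTrend:
    def test_constant_before_first_data_year(self, fitted_trend):
        import copy

        fit = copy.deepcopy(fitted_trend)
        fix_tail_trend(fit, "R0", 1995)
        values = fit.trend_values("R0", [1990, 1993, 1995])
        assert values[0] == values[1] == values[2]

    def test_late_window_returns_arithmetic_mean(self, fitted_trend):
        import copy

        fit = copy.deepcopy(fitted_trend)
        raw = fit.trend_values("R0", [2019, 2020, 2021])
        fix_tail_trend(fit, "R0", 1990, (2019, 2020, 2021))
        fixed = fit.trend_values("R0", [2019, 2020, 2021])
        np.testing.assert_allclose(fixed, raw.mean(), atol=1e-12)

    def test_pre_data_years_flat_without_covariates(self, fitted_trend):
        """Ablation: with no covariate terms, the predicted series before the
        first data year varies only through (constant) intercepts."""
        import copy

        fit = copy.deepcopy(fitted_trend)
        fix_tail_trend(fit, "R0", 2000)
        frame = pd.DataFrame({"country": "C00", "year": [1990, 1994, 1999]})
        rates = predict_frame(fit, frame)
        assert np.ptp(rates) < 1e-12

    def test_empty_window_rejected(self, fitted_trend):
        import copy

        with pytest.raises(ConfigurationError):
            fix_tail_trend(copy.deepcopy(fitted_trend), "R0", 1995, ())


class TestSampleCoefficients:
    def test_zero_covariance_returns_point_estimate(self, fitted_plain):
        import copy

        fit = copy.deepcopy(fitted_plain)
        fit.coef_covariance = np.zeros_like(fit.coef_covariance)
        draws = sample_coefficients(fit, 7, seed=0)
        assert draws.shape == (7, fit.coefficients.size)
        np.testing.assert_array_equal(draws, np.tile(fit.coefficients, (7, 1)))

    def test_draw_count_matches_request(self, fitted_plain):
        draws = sample_coefficients(fitted_plain, 100, seed=1)
        assert draws.shape == (100, fitted_plain.coefficients.size)

    def test_deterministic_given_seed(self, fitted_plain):
        np.testing.assert_array_equal(
            sample_coefficients(fitted_plain, 5, seed=3),
            sample_coefficients(fitted_plain, 5, seed=3),
        )

    def test_mean_of_many_draws_near_point(self, fitted_plain):
        draws = sample_coefficients(fitted_plain, 50_000, seed=2)
        se = np.sqrt(np.diag(fitted_plain.coef_covariance) / 50_000)
        np.testing.assert_array_less(
            np.abs(draws.mean(axis=0) - fitted_plain.coefficients), 3 * se + 1e-12
        )
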