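"""Unit tests for synchrony statistics, regressions and change metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosync import synchrony
from phenosync.cleaning import PixelPanel
from phenosync.exceptions import DegenerateInputError
from phenosync.synchrony import PixelRegression


def panel_from_dates(dates, years=None):
    dates = np.asarray(dates, dtype=float)
    n_ind, n_yr = dates.shape
    years = np.arange(2001, 2001 + n_yr) if years is None else np.asarray(years)
    return PixelPanel(
        pixel=(48, 11),
        species="Fagus sylvatica",
        phase="leafout_BBCH11",
        individuals=[f"i{k}" for k in range(n_ind)],
        years=years,
        dates=dates,
        altitudes=np.full(n_ind, 500.0),
        latitude=48.5,
        longitude=11.5,
    )


class TestComputeSynchrony:
    def test_los_is_sample_sd_of_dates(self, constant_climate):
        panel = panel_from_dates([[100.0], [102.0], [104.0]])
        table = synchrony.compute_synchrony(panel, constant_climate)
        assert table.loc[2001, "los"] == pytest.approx(2.0)

    def test_identical_dates_give_zero_synchrony_loss(self, constant_climate):
        panel = panel_from_dates([[100.0], [100.0], [100.0]])
        table = synchrony.compute_synchrony(panel, constant_climate)
        assert table.loc[2001, "los"] == 0.0
        assert table.loc[2001, "los_dd"] == 0.0

    def test_los_dd_from_hand_computed_forcing_sums(self, constant_climate):
        # dates 10 and 20 at constant 15 degC give DD sums 100 and 200
        panel = panel_from_dates([[10.0], [20.0]])
        table = synchrony.compute_synchrony(panel, constant_climate)
        assert table.loc[2001, "los_dd"] == pytest.approx(100.0 / np.sqrt(2.0))

    def test_constant_climate_identity_los_dd_equals_rate_times_los(
        self, constant_climate
    ):
        rng = np.random.default_rng(4)
        dates = rng.integers(80, 140, size=(5, 4)).astype(float)
        panel = panel_from_dates(dates)
        table = synchrony.compute_synchrony(panel, constant_climate)
        np.testing.assert_allclose(table["los_dd"], 10.0 * table["los"], rtol=1e-12)

    def test_translation_invariance_of_los(self, constant_climate):
        dates = np.array([[100.0, 95.0], [104.0, 99.0], [110.0, 101.0]])
        a = synchrony.compute_synchrony(panel_from_dates(dates), constant_climate)
        b = synchrony.compute_synchrony(panel_from_dates(dates + 7.0), constant_climate)
        np.testing.assert_allclose(a["los"], b["los"], atol=1e-12)

    def test_year_with_single_observation_flagged_missing(self, constant_climate):
        dates = np.array([[100.0, np.nan], [102.0, 101.0], [104.0, np.nan]])
        table = synchrony.compute_synchrony(panel_from_dates(dates), constant_climate)
        assert np.isnan(table.loc[2002, "los"])
        assert not np.isnan(table.loc[2001, "los"])


class TestPixelRegression:
    def test_exact_linear_relationship(self):
        table = pd.DataFrame(
            {"preseason_temp": [1.0, 2.0, 3.0, 4.0], "los": [2.0, 4.0, 6.0, 8.0]}
        )
        reg = synchrony.pixel_regression(table)
        assert reg.r == pytest.approx(1.0)
        assert reg.slope == pytest.approx(2.0)

    def test_constant_response_is_degenerate(self):
        table = pd.DataFrame({"preseason_temp": [1.0, 2.0, 3.0], "los": [5.0] * 3})
        with pytest.raises(DegenerateInputError):
            synchrony.pixel_regression(table)

    def test_too_few_years_is_degenerate(self):
        table = pd.DataFrame({"preseason_temp": [1.0, 2.0], "los": [1.0, 2.0]})
        with pytest.raises(DegenerateInputError):
            synchrony.pixel_regression(table)

    def test_planted_slope_recovered_within_sampling_error(self):
        # 20 years, slope 0.6 days/degC, noise SD 0.5: estimate within
        # +-0.35 in >= 90% of 100 seeds (OLS sampling distribution)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(2, 8, 20)
            y = 1.0 + 0.6 * x + rng.normal(0, 0.5, 20)
            reg = synchrony.pixel_regression(
                pd.DataFrame({"preseason_temp": x, "los": y})
            )
            hits += abs(reg.slope - 0.6) <= 0.35
        assert hits >= 90


def reg(r, p=0.01):
    return PixelRegression(r=r, slope=r, intercept=0.0, p_value=p, n_years=10)


class TestSummarizeCorrelations:
    def test_textbook_t_statistic(self):
        summary = synchrony.summarize_correlations([reg(0.1), reg(0.2), reg(0.3)])
        assert summary.mean_r == pytest.approx(0.2)
        assert summary.t_statistic == pytest.approx(0.2 / (0.1 / np.sqrt(3)), rel=1e-6)
        expected_p = 2 * stats.t.sf(summary.t_statistic, df=2)
        assert summary.p_value == pytest.approx(expected_p)
        assert summary.p_value == pytest.approx(0.0742, abs=5e-4)

    def test_all_positive_gives_100_percent(self):
        summary = synchrony.summarize_correlations([reg(0.2), reg(0.4), reg(0.1)])
        assert summary.pct_focal_sign == 100.0

    def test_single_pixel_rejected(self):
        with pytest.raises(DegenerateInputError):
            synchrony.summarize_correlations([reg(0.5)])

    def test_sign_mixture_fractions_exact(self):
        regs = [reg(0.5, 0.01)] * 6 + [reg(-0.5, 0.2)] * 4
        summary = synchrony.summarize_correlations(regs, focal_sign=1)
        assert summary.pct_focal_sign == 60.0
        assert summary.pct_significant == 60.0
        neg = synchrony.summarize_correlations(regs, focal_sign=-1)
        assert neg.pct_focal_sign == 40.0
        assert neg.pct_significant == 0.0  # negative pixels have p >= 0.05

    def test_identical_correlations_flagged_degenerate(self):
        summary = synchrony.summarize_correlations([reg(0.3), reg(0.3)])
        assert summary.degenerate and np.isnan(summary.t_statistic)


def simulate_tidy(seed, n_pixels=8, n_years=12, slope=0.61, pixel_sd=1.0, noise_sd=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    intercepts = rng.normal(5.0, pixel_sd, n_pixels)
    for p in range(n_pixels):
        x = rng.uniform(2, 8, n_years)
        y = intercepts[p] + slope * x + rng.normal(0, noise_sd, n_years)
        for xi, yi in zip(x, y):
            rows.append({"pixel": f"p{p}", "preseason_temp": xi, "los": yi})
    return pd.DataFrame(rows)


class TestDistributionModel:
    mcmc = dict(chains=2, iterations=1500, burnin=500)

    def test_planted_slope_inside_credible_interval_most_seeds(self):
        hits = 0
        for seed in range(20):
            fit = synchrony.fit_distribution_model(
                simulate_tidy(seed), seed=seed, **self.mcmc
            )
            lo, hi = fit.slope_ci
            hits += lo <= 0.61 <= hi
        assert hits >= 17

    def test_zero_slope_interval_covers_zero(self):
        fit = synchrony.fit_distribution_model(
            simulate_tidy(1, slope=0.0), seed=0, **self.mcmc
        )
        assert fit.slope_ci[0] <= 0.0 <= fit.slope_ci[1]

    def test_no_pixel_heterogeneity_gives_small_random_intercept_variance(self):
        fit = synchrony.fit_distribution_model(
            simulate_tidy(2, pixel_sd=0.0), seed=0, **self.mcmc
        )
        assert fit.pixel_variance < 0.1 * fit.residual_variance + 0.05

    def test_single_pixel_collapses_to_ols_with_warning(self):
        table = simulate_tidy(3, n_pixels=1)
        with pytest.warns(UserWarning, match="single pixel"):
            fit = synchrony.fit_distribution_model(table, **self.mcmc)
        assert fit.collapsed_to_ols
        ols = stats.linregress(table["preseason_temp"], table["los"])
        assert fit.slope == pytest.approx(ols.slope)

    def test_slope_agrees_with_reml_mixed_model(self):
        """Independent oracle: statsmodels MixedLM on the same data."""
        import statsmodels.formula.api as smf

        table = simulate_tidy(4)
        fit = synchrony.fit_distribution_model(table, seed=0, **self.mcmc)
        lme = smf.mixedlm("los ~ preseason_temp", table, groups=table["pixel"]).fit()
        se = lme.bse["preseason_temp"]
        assert fit.slope == pytest.approx(lme.params["preseason_temp"], abs=3 * se)


class TestChangeMetrics:
    def fit(self, intercept, slope):
        return synchrony.DistributionModelFit(
            slope=slope,
            slope_ci=(slope, slope),
            intercept=intercept,
            pixel_variance=0.0,
            residual_variance=1.0,
            response="los",
            predictor="preseason_temp",
        )

    def test_closed_form_example(self):
        # SD 5.1 -> 7.9: +54.9% and 3.92 x 2.8 = 10.98 days of lengthening
        model = self.fit(intercept=5.1, slope=2.8)  # SD(0)=5.1, SD(1)=7.9
        pct, days = synchrony.synchrony_change_metrics(model, 0.0, 1.0)
        assert pct == pytest.approx(54.901960, rel=1e-6)
        assert days == pytest.approx(10.976, abs=1e-3)

    def test_no_change(self):
        pct, days = synchrony.synchrony_change_metrics(self.fit(5.0, 0.0), 0.0, 3.0)
        assert pct == 0.0 and days == 0.0

    def test_sd_doubling(self):
        model = self.fit(intercept=4.0, slope=4.0)  # SD doubles from 0 to 1
        pct, days = synchrony.synchrony_change_metrics(model, 0.0, 1.0)
        assert pct == pytest.approx(100.0)
        assert days == pytest.approx(3.92 * 4.0)

    def test_nonpositive_cold_sd_rejected(self):
        with pytest.raises(DegenerateInputError):
            synchrony.synchrony_change_metrics(self.fit(-1.0, 1.0), 0.0, 1.0)
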