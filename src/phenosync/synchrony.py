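"""Within-population synchrony statistics and their response to temperature.

Synchrony is measured per pixel and year as the standard deviation of
event dates among individuals (LOS for leaf-out, FLS for flowering) and,
in parallel, as the standard deviation of the degree-day sums individuals
had accumulated by their event (LOS-DD / FLS-DD).  Per-pixel ordinary
least squares against preseason temperature, cross-pixel correlation
summaries, a random-intercept distribution model, and the derived
"95% window" change metrics live here.

Sample standard deviations (n-1 denominator) are used throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import drivers
from .cleaning import PixelPanel
from .climate import ClimateSeries
from .exceptions import DegenerateInputError, InvalidParameterError

#: Width of the central 95% range of a normal distribution, in SDs (2 x 1.96).
WINDOW_95_FACTOR = 3.92


def compute_synchrony(
    panel: PixelPanel,
    climate: ClimateSeries,
    preseason_window: int = 60,
    base: float = drivers.BASE_TEMP_C,
    per_year_window: bool = False,
) -> pd.DataFrame:
    """Per-year synchrony series for one panel.

    Returns a frame indexed by year with columns ``los`` (SD of dates,
    days), ``los_dd`` (SD of individual degree-day sums), ``mean_doy``,
    ``preseason_temp``, ``mean_chilling`` (mean chilling hours until the
    individual events) and ``dl_at_forcing`` (day length on the day the
    population-average forcing requirement is met).  Years with fewer
    than two observed individuals are NaN-flagged, not dropped.

    The preseason window is anchored, by default, at the panel's long-term
    mean event date (one fixed window per pixel); ``per_year_window``
    anchors it at each year's own mean date instead.
    """
    years = [int(y) for y in panel.years]
    usable = [y for y in years if y > climate.start_year and y in set(climate.years)]
    if not usable:
        raise InvalidParameterError("climate does not cover any panel year")

    long_term_mean = float(np.nanmean(panel.dates))
    fixed_anchor = int(round(long_term_mean))

    # Per-individual forcing requirement (DD sum at the individual's event),
    # averaged across years, then across individuals: the population-average
    # requirement whose fulfilment date defines dl_at_forcing.
    dd_matrix = np.full_like(panel.dates, np.nan)
    for j, year in enumerate(years):
        if year not in set(climate.years):
            continue
        cdd = drivers.degree_day_cumsum(climate.daily_for(year), base)
        col = panel.dates[:, j]
        ok = ~np.isnan(col)
        dd_matrix[ok, j] = cdd[col[ok].astype(int) - 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_req = float(np.nanmean(np.nanmean(dd_matrix, axis=1)))

    rows = []
    for j, year in enumerate(years):
        if year not in usable:
            continue
        col = panel.dates[:, j]
        ok = ~np.isnan(col)
        row = {
            "year": year,
            "los": np.nan,
            "los_dd": np.nan,
            "mean_doy": np.nan,
            "preseason_temp": np.nan,
            "mean_chilling": np.nan,
            "dl_at_forcing": np.nan,
        }
        daily = climate.daily_for(year)
        if ok.sum() >= 2:
            dates = col[ok]
            row["los"] = float(np.std(dates, ddof=1))
            row["los_dd"] = float(np.std(dd_matrix[ok, j], ddof=1))
            row["mean_doy"] = float(dates.mean())
            anchor = int(round(dates.mean())) if per_year_window else fixed_anchor
            # anchor on a two-year series so the window may reach into December
            prev = climate.daily_for(year - 1)
            row["preseason_temp"] = drivers.preseason_temperature(
                np.concatenate([prev, daily]), prev.size + anchor, preseason_window
            )
            ch_cum = climate.chilling_cumulative(year)
            row["mean_chilling"] = float(
                np.mean(ch_cum[dates.astype(int) - 1])
            )
            fdoy = drivers.forcing_fulfilment_doy(daily, mean_req, base=base)
            if fdoy is not None:
                row["dl_at_forcing"] = drivers.day_length(
                    climate.latitude, fdoy
                ).hours
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


@dataclass(frozen=True)
class PixelRegression:
    """OLS of a synchrony response on one driver within a pixel."""

    r: float
    slope: float
    intercept: float
    p_value: float
    n_years: int
    predictor: str = "preseason_temp"
    response: str = "los"


def pixel_regression(
    series: pd.DataFrame,
    predictor: str = "preseason_temp",
    response: str = "los",
) -> PixelRegression:
    """Ordinary least squares of ``response`` on ``predictor`` across years.

    Two-sided p-value from the t distribution with n-2 degrees of freedom.
    Fewer than three complete years, or a zero-variance predictor or
    response, raise :class:`DegenerateInputError`.
    """
    data = series[[predictor, response]].dropna()
    n = len(data)
    if n < 3:
        raise DegenerateInputError(f"only {n} complete years (need >= 3)")
    x = data[predictor].to_numpy()
    y = data[response].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance predictor or response")
    fit = stats.linregress(x, y)
    return PixelRegression(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_years=n,
        predictor=predictor,
        response=response,
    )


@dataclass(frozen=True)
class CorrelationSummary:
    """Cross-pixel summary of per-pixel correlation coefficients."""

    mean_r: float
    ci95_halfwidth: float
    pct_focal_sign: float
    pct_significant: float
    t_statistic: float
    p_value: float
    n_pixels: int
    focal_sign: int
    degenerate: bool = False


def summarize_correlations(
    regressions: list[PixelRegression],
    alpha: float = 0.05,
    focal_sign: int | None = None,
) -> CorrelationSummary:
    """Summarize per-pixel correlations: mean r, t-based CI, sign shares.

    ``focal_sign`` (+1 or -1) selects which sign the percentage columns
    count; by default it is the sign of the mean correlation.  The
    significant share counts pixels with the focal sign *and* p < alpha.
    A one-sample two-sided t-test asks whether the mean r differs from 0;
    if all r are identical the test is undefined and the summary is
    flagged degenerate.
    """
    if len(regressions) < 2:
        raise DegenerateInputError("need at least two pixels to summarize")
    r = np.array([reg.r for reg in regressions])
    p = np.array([reg.p_value for reg in regressions])
    n = r.size
    mean_r = float(r.mean())
    sd = float(r.std(ddof=1))
    sign = focal_sign if focal_sign is not None else (1 if mean_r >= 0 else -1)
    with_sign = np.sign(r) == sign
    pct_sign = 100.0 * with_sign.mean()
    pct_sig = 100.0 * (with_sign & (p < alpha)).mean()
    if sd == 0:
        return CorrelationSummary(
            mean_r=mean_r,
            ci95_halfwidth=0.0,
            pct_focal_sign=pct_sign,
            pct_significant=pct_sig,
            t_statistic=math.nan,
            p_value=math.nan,
            n_pixels=n,
            focal_sign=sign,
            degenerate=True,
        )
    t_stat = mean_r / (sd / math.sqrt(n))
    p_val = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return CorrelationSummary(
        mean_r=mean_r,
        ci95_halfwidth=half,
        pct_focal_sign=pct_sign,
        pct_significant=pct_sig,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_pixels=n,
        focal_sign=sign,
    )


@dataclass
class DistributionModelFit:
    """Random-intercept regression of a response on preseason temperature."""

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    pixel_variance: float
    residual_variance: float
    response: str
    predictor: str
    posterior: object | None = None
    collapsed_to_ols: bool = False

    def predict(self, x: float) -> float:
        """Population-level prediction at predictor value ``x``."""
        return self.intercept + self.slope * x


def fit_distribution_model(
    table: pd.DataFrame,
    response: str = "los",
    predictor: str = "preseason_temp",
    pixel_col: str = "pixel",
    chains: int = 3,
    iterations: int = 4000,
    burnin: int = 1000,
    seed: int = 0,
) -> DistributionModelFit:
    """Model a synchrony response across pixels with a pixel random intercept.

    ``table`` is tidy (one row per pixel-year).  The model is the Bayesian
    random-intercept regression from :mod:`phenosync.hbayes` on the raw
    (unstandardized) scale, so the slope is directly in response units per
    predictor unit; posterior means are reported as estimates with a
    central 95% credible interval on the slope.  With a single pixel the
    random intercept is unidentifiable and the fit collapses to OLS, with
    a warning.
    """
    from . import hbayes

    data = table[[response, predictor, pixel_col]].dropna()
    pixels = data[pixel_col].unique()
    if len(pixels) < 2:
        warnings.warn("single pixel: collapsing to ordinary least squares")
        fit = stats.linregress(data[predictor], data[response])
        se = fit.stderr
        return DistributionModelFit(
            slope=float(fit.slope),
            slope_ci=(float(fit.slope - 1.96 * se), float(fit.slope + 1.96 * se)),
            intercept=float(fit.intercept),
            pixel_variance=0.0,
            residual_variance=float(np.var(
                data[response] - fit.intercept - fit.slope * data[predictor], ddof=2
            )),
            response=response,
            predictor=predictor,
            collapsed_to_ols=True,
        )
    hb = hbayes.HBData.from_frame(
        data,
        response=response,
        predictors=[predictor],
        pixel_col=pixel_col,
        standardize=False,
    )
    post = hbayes.fit_hb_model(
        hb, chains=chains, iterations=iterations, burnin=burnin, seed=seed
    )
    summ = post.summary()
    beta = summ.loc[f"beta[{predictor}]"]
    return DistributionModelFit(
        slope=float(beta["mean"]),
        slope_ci=(float(beta["q2.5"]), float(beta["q97.5"])),
        intercept=float(summ.loc["alpha", "mean"]),
        pixel_variance=float(summ.loc["tau2_pixel", "mean"]),
        residual_variance=float(summ.loc["sigma2", "mean"]),
        response=response,
        predictor=predictor,
        posterior=post,
    )


def synchrony_change_metrics(
    model: DistributionModelFit,
    temp_cold: float,
    temp_warm: float,
) -> tuple[float, float]:
    """Percent SD increase and 95%-window lengthening between two climates.

    The fitted distribution model predicts the within-pixel SD of event
    dates at a cold and a warm preseason temperature.  Under a normal
    model of within-pixel dates, 95% of individuals fall inside a window
    of width 3.92 SD, so the window lengthens by ``3.92 (SD_warm -
    SD_cold)`` days while the SD changes by ``100 (SD_warm - SD_cold) /
    SD_cold`` percent.
    """
    sd_cold = model.predict(temp_cold)
    sd_warm = model.predict(temp_warm)
    if sd_cold <= 0:
        raise DegenerateInputError(f"predicted cold-climate SD {sd_cold} <= 0")
    pct = 100.0 * (sd_warm - sd_cold) / sd_cold
    lengthening = WINDOW_95_FACTOR * (sd_warm - sd_cold)
    return pct, lengthening


def regressions_to_frame(regressions: list[PixelRegression]) -> pd.DataFrame:
    """Tabulate per-pixel regressions (one row per pixel)."""
    return pd.DataFrame([vars(r) for r in regressions])
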