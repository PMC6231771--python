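"""Degree-day-only null model of synchrony loss.

If phenology were driven purely by degree-day accumulation — no day
length, no chilling — how much of the synchrony loss under warm
preseasons would the shape of the spring temperature curve alone
produce?  Individuals differ only in a fixed forcing requirement drawn
once; each year their event date is the day the requirement is
fulfilled, and the per-year SD of dates is regressed on preseason
temperature.  The resulting coefficient (SD-days per degC) is the null
against which the trait-heterogeneity mechanism is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import drivers
from .climate import ClimateSeries
from .exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    MissingDataError,
)
from .synchrony import PixelRegression, pixel_regression

import pandas as pd


@dataclass(frozen=True)
class DDNullConfig:
    """Configuration of the degree-day-only simulation.

    Defaults mirror the synthetic population defaults: ~105 degree-day
    mean requirement with ~10% between-individual spread.
    """

    forcing_req_mean: float = 105.0
    forcing_req_sd: float = 10.5
    n_individuals: int = 50
    seed: int = 0
    base: float = drivers.BASE_TEMP_C
    preseason_window: int = 60
    redraw_each_year: bool = False
    #: explicit per-individual requirements; overrides the normal draw
    requirements: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.forcing_req_sd < 0:
            raise InvalidParameterError("forcing_req_sd must be non-negative")
        n = self.n_individuals if self.requirements is None else len(self.requirements)
        if n < 2:
            raise InvalidParameterError("need at least two individuals")


@dataclass
class DDNullResult:
    """Per-year dates and the SD-vs-temperature regression of the null."""

    years: np.ndarray
    dates: np.ndarray  # (n_years, n_individuals), NaN for unfulfilled years
    sd_by_year: np.ndarray
    preseason_temp: np.ndarray
    incomplete_years: list[int]
    regression: PixelRegression | None
    degenerate: bool = False

    @property
    def slope(self) -> float:
        """SD-days per degC of preseason warming (NaN when degenerate)."""
        return self.regression.slope if self.regression is not None else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "sd_dates": self.sd_by_year,
                "preseason_temp": self.preseason_temp,
            }
        ).set_index("year")


def simulate_dd_only(config: DDNullConfig, climate: ClimateSeries) -> DDNullResult:
    """Run the degree-day-only simulation over every climate year.

    Requirements are drawn once per individual (fixed individual
    differences) unless ``redraw_each_year`` is set.  Years in which any
    individual's requirement is never fulfilled are flagged incomplete
    and excluded from the regression.  A zero-variance outcome (e.g.
    ``forcing_req_sd = 0``) leaves the regression degenerate-flagged
    rather than raising.
    """
    rng = np.random.default_rng(config.seed)

    def _draw() -> np.ndarray:
        if config.requirements is not None:
            return np.asarray(config.requirements, dtype=float)
        req = rng.normal(config.forcing_req_mean, config.forcing_req_sd, config.n_individuals)
        return np.maximum(req, 0.05 * config.forcing_req_mean)

    requirements = _draw()
    years = climate.years
    n_years = years.size
    dates = np.full((n_years, requirements.size), np.nan)
    sd = np.full(n_years, np.nan)
    preseason = np.full(n_years, np.nan)
    incomplete: list[int] = []

    for i, year in enumerate(years):
        if config.redraw_each_year:
            requirements = _draw()
        daily = climate.daily_for(year)
        cdd = drivers.degree_day_cumsum(daily, config.base)
        idx = np.searchsorted(cdd, requirements, side="left")
        unfulfilled = idx >= cdd.size
        if unfulfilled.any():
            incomplete.append(int(year))
            continue
        dates[i] = idx + 1.0
        sd[i] = float(np.std(dates[i], ddof=1))
        mean_doy = int(round(dates[i].mean()))
        # extend into the preceding December when the window needs it
        if i > 0:
            prev = climate.daily_for(year - 1)
            preseason[i] = drivers.preseason_temperature(
                np.concatenate([prev, daily]),
                prev.size + mean_doy,
                config.preseason_window,
            )
        else:
            try:
                preseason[i] = drivers.preseason_temperature(
                    daily, mean_doy, config.preseason_window
                )
            except MissingDataError:
                incomplete.append(int(year))

    frame = pd.DataFrame({"preseason_temp": preseason, "sd_dates": sd})
    try:
        reg = pixel_regression(frame, predictor="preseason_temp", response="sd_dates")
        degenerate = False
    except DegenerateInputError:
        reg = None
        degenerate = True
    return DDNullResult(
        years=years,
        dates=dates,
        sd_by_year=sd,
        preseason_temp=preseason,
        incomplete_years=incomplete,
        regression=reg,
        degenerate=degenerate,
    )
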