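"""Synthetic climate and within-population phenology.

Generates the two kinds of input the synchrony analysis consumes without
any external download:

* multi-year temperature series with a seasonal cycle, a linear warming
  trend, year-level offsets and AR(1) day-to-day noise (a stand-in for
  gridded reanalysis temperature), with sub-daily values derived from a
  sinusoidal diurnal cycle so chilling hours can be computed;
* individual spring event dates produced by a forcing (degree-day) model
  in which each individual's requirement is modulated linearly by day
  length and accumulated chilling, emulating the within-population trait
  heterogeneity seen in twig-cutting experiments.

The trait model: individual *i* leafs out on the first day *t* with

    DD(1 Jan .. t)  >=  max(F_i + s_dl,i (DL(t) - 16 h)
                               + s_ch,i (Ch(t) - Ch_ref),  floor)

where ``F_i`` is the forcing requirement under long days and full
chilling, ``s_dl,i <= 0`` the day-length sensitivity (degree-days per
hour), ``s_ch,i <= 0`` the chilling sensitivity (degree-days per chilling
hour), DL the day length and Ch the chilling hours since 1 November of
the preceding year.  The linear form mirrors how the sensitivities are
defined experimentally (as slopes); it is a modelling choice, not an
observed law.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import drivers
from .exceptions import InvalidParameterError

DAYS_PER_YEAR = 365
#: DOY of 1 November (non-leap calendar used throughout).
NOV1_DOY = 305

_RESOLUTIONS = {"daily": 24.0, "hourly": 1.0, "6-hourly": 6.0}

#: Day length (h) at which day-length-sensitive requirements are referenced:
#: at 16 h and above the photoperiod requirement is considered fully met.
DAYLENGTH_REF_H = 16.0

#: Reference chilling (hours) at which the chilling requirement is met.
CHILL_REF_H = 1200.0


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic temperature generator.

    Defaults describe a central-European lowland site: 9 degC annual mean
    with a 10 degC seasonal half-amplitude, 1 degC between-year offsets,
    2 degC daily noise with AR(1) persistence 0.7, and a 4 degC diurnal
    half-amplitude for the derived sub-daily series.
    """

    annual_mean: float = 9.0
    seasonal_amplitude: float = 10.0
    warming_trend: float = 0.0
    year_offsets_sd: float = 1.0
    noise_sd: float = 2.0
    noise_autocorr: float = 0.7
    resolution: str = "hourly"
    n_years: int = 20
    seed: int = 0
    latitude: float = 48.5
    longitude: float = 11.5
    start_year: int = 2000
    diurnal_amplitude: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_autocorr < 1:
            raise InvalidParameterError("noise_autocorr must lie in [0, 1)")
        if self.n_years < 1:
            raise InvalidParameterError("n_years must be at least 1")
        if self.resolution not in _RESOLUTIONS:
            raise InvalidParameterError(
                f"resolution must be one of {sorted(_RESOLUTIONS)}"
            )
        for name in ("year_offsets_sd", "noise_sd", "diurnal_amplitude"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


@dataclass
class ClimateSeries:
    """Daily temperatures for one site over consecutive years.

    ``daily`` has shape (n_years, 365); column d-1 is DOY d.  Sub-daily
    values are derived on demand from a diurnal cosine peaking at 14:00
    whose mean over any full day equals the daily mean.
    """

    daily: np.ndarray
    start_year: int
    latitude: float
    longitude: float = 11.5
    diurnal_amplitude: float = 4.0
    step_hours: float = 1.0
    site_id: str = "site"
    year_offsets: np.ndarray | None = None

    @property
    def n_years(self) -> int:
        return self.daily.shape[0]

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)

    def year_index(self, year: int) -> int:
        idx = int(year) - self.start_year
        if not 0 <= idx < self.n_years:
            raise InvalidParameterError(f"year {year} outside the series")
        return idx

    def daily_for(self, year: int) -> np.ndarray:
        return self.daily[self.year_index(year)]

    def subdaily_for(self, year: int, step_hours: float | None = None) -> np.ndarray:
        """Sub-daily temperatures for one year, diurnal cycle superposed."""
        step = self.step_hours if step_hours is None else step_hours
        return _subdaily(self.daily_for(year), self.diurnal_amplitude, step)

    def chilling_window(
        self, year: int, t_end_doy: int, step_hours: float | None = None
    ) -> np.ndarray:
        """Sub-daily series from 1 Nov of the preceding year through t_end_doy."""
        step = self.step_hours if step_hours is None else step_hours
        prev = self.daily_for(year - 1)[NOV1_DOY - 1 :]
        cur = self.daily_for(year)[:t_end_doy]
        return _subdaily(np.concatenate([prev, cur]), self.diurnal_amplitude, step)

    def chilling_cumulative(
        self, year: int, step_hours: float | None = None
    ) -> np.ndarray:
        """Chilling hours from 1 Nov of year-1 through each DOY of ``year``.

        Element d-1 is Ch_sum through the end of DOY d.
        """
        step = self.step_hours if step_hours is None else step_hours
        prev = self.daily_for(year - 1)[NOV1_DOY - 1 :]
        full = _subdaily(np.concatenate([prev, self.daily_for(year)]), self.diurnal_amplitude, step)
        in_band = (full >= drivers.CHILL_MIN_C) & (full <= drivers.CHILL_MAX_C)
        per_step = in_band.astype(float) * step
        steps_per_day = int(round(24.0 / step))
        per_day = per_step.reshape(-1, steps_per_day).sum(axis=1)
        n_prev = prev.size
        carry = per_day[:n_prev].sum()
        return carry + np.cumsum(per_day[n_prev:])

    def warmed(self, delta: float) -> "ClimateSeries":
        """A copy with every temperature raised by ``delta`` degC."""
        return replace(self, daily=self.daily + float(delta))


def _subdaily(daily: np.ndarray, amplitude: float, step_hours: float) -> np.ndarray:
    if step_hours not in (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0):
        raise InvalidParameterError("step_hours must divide 24")
    steps = int(round(24.0 / step_hours))
    hours = (np.arange(steps) + 0.5) * step_hours
    cycle = amplitude * np.cos(2.0 * np.pi * (hours - 14.0) / 24.0)
    cycle -= cycle.mean()  # exact zero-mean so daily means are preserved
    return (daily[:, None] + cycle[None, :]).ravel()


def generate_temperature_series(params: ClimateParams) -> ClimateSeries:
    """Generate a multi-year daily temperature series.

    Daily value at DOY d of year index y (0-based):

        annual_mean + warming_trend * y + offset_y
        + seasonal_amplitude * cos(2 pi (d - 200) / 365) + AR(1) noise,

    so the seasonal cycle peaks near DOY 200 (mid-July).  The AR(1) noise
    is continuous across year boundaries with stationary SD ``noise_sd``.
    Identical parameters (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n, d = params.n_years, DAYS_PER_YEAR
    doy = np.arange(1, d + 1)
    seasonal = params.seasonal_amplitude * np.cos(2.0 * np.pi * (doy - 200) / d)
    offsets = rng.normal(0.0, params.year_offsets_sd, size=n) if params.year_offsets_sd > 0 else np.zeros(n)
    year_level = params.annual_mean + params.warming_trend * np.arange(n) + offsets

    noise = np.zeros(n * d)
    if params.noise_sd > 0:
        rho = params.noise_autocorr
        z = rng.standard_normal(n * d)
        noise[0] = params.noise_sd * z[0]
        innov_sd = params.noise_sd * np.sqrt(1.0 - rho**2)
        for t in range(1, n * d):
            noise[t] = rho * noise[t - 1] + innov_sd * z[t]

    daily = year_level[:, None] + seasonal[None, :] + noise.reshape(n, d)
    return ClimateSeries(
        daily=daily,
        start_year=params.start_year,
        latitude=params.latitude,
        longitude=params.longitude,
        diurnal_amplitude=params.diurnal_amplitude,
        step_hours=_RESOLUTIONS[params.resolution],
        year_offsets=offsets,
    )


@dataclass(frozen=True)
class IndividualTraits:
    """Leaf-out cue requirements of one individual.

    ``forcing_req`` is the degree-day requirement under long days (>= 16 h)
    and full chilling; the two sensitivities are slopes (degree-days per
    hour of day length, degree-days per chilling hour), non-positive for
    sensitive individuals.
    """

    id: str
    forcing_req: float
    daylength_sensitivity: float = 0.0
    chilling_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if self.forcing_req <= 0:
            raise InvalidParameterError("forcing_req must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Trait distribution of a synthetic population at one site.

    Defaults give a beech-like population: a ~105 degree-day mean forcing
    requirement with 12 DD between-individual spread, strongly heterogeneous
    day-length sensitivity (mean -12 DD/h, SD 8, truncated at 0 so no
    individual is anti-sensitive) and weak, homogeneous chilling
    sensitivity.
    """

    n_individuals: int = 12
    forcing_req_mean: float = 105.0
    forcing_req_sd: float = 12.0
    daylength_sens_mean: float = -12.0
    daylength_sens_sd: float = 8.0
    chilling_sens_mean: float = -0.02
    chilling_sens_sd: float = 0.01
    latitude: float = 48.5
    longitude: float = 11.5
    altitude_mean: float = 500.0
    altitude_sd: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be at least 1")
        for name in (
            "forcing_req_sd",
            "daylength_sens_sd",
            "chilling_sens_sd",
            "altitude_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


def draw_population(
    spec: PopulationSpec,
) -> tuple[list[IndividualTraits], np.ndarray]:
    """Draw individual traits and altitudes from a population spec.

    Forcing requirements are truncated below at 10% of the mean (redrawn
    values never reach zero); sensitivities are truncated above at 0, so
    the least sensitive individuals are exactly insensitive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    forcing = rng.normal(spec.forcing_req_mean, spec.forcing_req_sd, n)
    forcing = np.maximum(forcing, 0.1 * spec.forcing_req_mean)
    dl = np.minimum(rng.normal(spec.daylength_sens_mean, spec.daylength_sens_sd, n), 0.0)
    ch = np.minimum(rng.normal(spec.chilling_sens_mean, spec.chilling_sens_sd, n), 0.0)
    altitudes = rng.normal(spec.altitude_mean, spec.altitude_sd, n)
    traits = [
        IndividualTraits(
            id=f"ind{i:03d}",
            forcing_req=float(forcing[i]),
            daylength_sensitivity=float(dl[i]),
            chilling_sensitivity=float(ch[i]),
        )
        for i in range(n)
    ]
    return traits, altitudes


def simulate_events(
    traits: list[IndividualTraits],
    climate: ClimateSeries,
    altitudes: np.ndarray | None = None,
    chill_ref: float = CHILL_REF_H,
    daylength_ref: float = DAYLENGTH_REF_H,
    requirement_floor: float = 1.0,
    species: str = "Fagus sylvatica",
    phase: str = "leafout_BBCH11",
) -> pd.DataFrame:
    """Simulate event dates for every individual and usable year.

    The first climate year is used only to supply the preceding-winter
    chilling of the second year, so records start at ``start_year + 1``.
    Years in which an individual's effective requirement is never reached
    appear with ``doy = NaN`` — an explicit missing flag, never a silently
    dropped row.

    Returns a tidy frame with columns
    ``series_id, species, phase, lat, lon, alt_m, year, doy``.
    """
    if climate.n_years < 2:
        raise InvalidParameterError(
            "climate must cover at least two years (chilling needs the preceding winter)"
        )
    if altitudes is None:
        altitudes = np.zeros(len(traits))
    altitudes = np.asarray(altitudes, dtype=float)
    if altitudes.size != len(traits):
        raise InvalidParameterError("one altitude per individual required")

    forcing = np.array([t.forcing_req for t in traits])
    s_dl = np.array([t.daylength_sensitivity for t in traits])
    s_ch = np.array([t.chilling_sensitivity for t in traits])
    dl = drivers.day_length_hours(climate.latitude, np.arange(1, DAYS_PER_YEAR + 1))

    rows = []
    for year in climate.years[1:]:
        cdd = drivers.degree_day_cumsum(climate.daily_for(year))
        ch_cum = climate.chilling_cumulative(year)
        f_eff = (
            forcing[:, None]
            + s_dl[:, None] * (dl - daylength_ref)[None, :]
            + s_ch[:, None] * (ch_cum - chill_ref)[None, :]
        )
        f_eff = np.maximum(f_eff, requirement_floor)
        reached = cdd[None, :] >= f_eff
        first = reached.argmax(axis=1)
        missing = ~reached.any(axis=1)
        doys = np.where(missing, np.nan, first + 1.0)
        for i, trait in enumerate(traits):
            rows.append(
                {
                    "series_id": trait.id,
                    "species": species,
                    "phase": phase,
                    "lat": climate.latitude,
                    "lon": climate.longitude,
                    "alt_m": float(altitudes[i]),
                    "year": int(year),
                    "doy": doys[i],
                }
            )
    return pd.DataFrame(rows)


def simulate_population(
    spec: PopulationSpec,
    climate: ClimateSeries,
    **kwargs,
) -> pd.DataFrame:
    """Draw a population from ``spec`` and simulate its event dates."""
    traits, altitudes = draw_population(spec)
    return simulate_events(traits, climate, altitudes=altitudes, **kwargs)


def emit_records(events: pd.DataFrame, path) -> pd.DataFrame:
    """Write simulated events as a PEP-style observation CSV.

    Missing-event years (doy = NaN) are omitted from the file; the
    returned frame is exactly what was written.
    """
    out = events.dropna(subset=["doy"]).copy()
    out["doy"] = out["doy"].astype(int)
    out["year"] = out["year"].astype(int)
    out.to_csv(path, index=False)
    return out
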