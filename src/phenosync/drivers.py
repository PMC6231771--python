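"""Environmental drivers of spring phenology.

Pure computations on temperature series and calendar coordinates:

* growing degree-days above a base temperature (forcing),
* chilling hours (time spent between 0 and 5 degC from 1 November),
* astronomical day length as a function of latitude and day-of-year
  (the CBM model of Forsythe and colleagues),
* preseason temperature (mean over a fixed window before the event),
* the day-of-year on which a forcing requirement is fulfilled.

Daily series are 1-D arrays indexed by day-of-year: ``temps[0]`` is DOY 1
(1 January).  Sub-daily series are 1-D arrays at a fixed step that divides
24 h.  All temperatures are degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, MissingDataError, ResolutionError

#: Base temperature (degC) above which degree-days accumulate.
BASE_TEMP_C = 5.0

#: Chilling is accrued while the mean temperature lies in [CHILL_MIN, CHILL_MAX].
CHILL_MIN_C = 0.0
CHILL_MAX_C = 5.0

# CBM day-length model constants (Forsythe et al. 1995).  The daylight
# coefficient p = 0.8333 degrees includes civil twilight at sunrise/sunset;
# 0.39795 = sin(obliquity of the ecliptic).
_CBM_P_DEG = 0.8333
_CBM_SIN_OBLIQUITY = 0.39795


@dataclass(frozen=True)
class ForcingSum:
    """Accumulated degree-days over a window of a daily series."""

    dd_sum: float
    t0: int
    t_end: int
    base: float = BASE_TEMP_C

    def __post_init__(self) -> None:
        if self.dd_sum < 0:
            raise InvalidParameterError("degree-day sum cannot be negative")
        if self.t0 > self.t_end:
            raise InvalidParameterError("t0 must not exceed t_end")


@dataclass(frozen=True)
class ChillingSum:
    """Accumulated chilling hours over a window of a sub-daily series."""

    ch_sum: float
    hours_elapsed: float

    def __post_init__(self) -> None:
        if not 0 <= self.ch_sum <= self.hours_elapsed + 1e-9:
            raise InvalidParameterError(
                "chilling hours must lie between 0 and the elapsed hours"
            )


@dataclass(frozen=True)
class DayLength:
    """Day length (hours) with the intermediate solar quantities."""

    hours: float
    latitude: float
    doy: int
    declination_rad: float
    solar_angle_rad: float


def degree_days(
    temps: np.ndarray,
    t0: int,
    t_end: int,
    base: float = BASE_TEMP_C,
) -> ForcingSum:
    """Accumulated degree-days over the inclusive window [t0, t_end].

    Each day contributes ``max(T - base, 0)``; days at or below the base
    temperature contribute nothing (standard growing-degree-day clamp).

    Parameters
    ----------
    temps
        Daily mean temperatures, ``temps[0]`` = DOY 1.
    t0, t_end
        1-based day-of-year bounds, both included in the sum.
    base
        Base temperature in degC (default 5).
    """
    temps = np.asarray(temps, dtype=float)
    if not 1 <= t0 <= t_end:
        raise InvalidParameterError(f"invalid window [{t0}, {t_end}]")
    if t_end > temps.size:
        raise MissingDataError(
            f"series of length {temps.size} does not cover DOY {t_end}"
        )
    window = temps[t0 - 1 : t_end]
    if np.isnan(window).any():
        raise MissingDataError("temperature gap inside the degree-day window")
    dd = float(np.clip(window - base, 0.0, None).sum())
    return ForcingSum(dd_sum=dd, t0=t0, t_end=t_end, base=base)


def degree_day_cumsum(temps: np.ndarray, base: float = BASE_TEMP_C) -> np.ndarray:
    """Cumulative degree-days from DOY 1; element d-1 is the sum through DOY d."""
    temps = np.asarray(temps, dtype=float)
    return np.cumsum(np.clip(temps - base, 0.0, None))


def chilling_hours(
    temps: np.ndarray,
    step_hours: float,
    t_min: float = CHILL_MIN_C,
    t_max: float = CHILL_MAX_C,
) -> ChillingSum:
    """Chilling hours accrued by a sub-daily series.

    Every time step whose mean temperature lies in ``[t_min, t_max]``
    (inclusive at both ends) contributes its step length in hours, so a
    6-hourly step at 2 degC contributes 6 h.

    Parameters
    ----------
    temps
        Sub-daily mean temperatures covering the accumulation window
        (conventionally starting 1 November of the preceding year).
    step_hours
        Time step in hours; must be positive, at most 24, and divide 24.
    """
    if not 0 < step_hours <= 24:
        raise ResolutionError(f"step of {step_hours} h unusable (must be in (0, 24])")
    if abs(24 / step_hours - round(24 / step_hours)) > 1e-9:
        raise ResolutionError(f"step of {step_hours} h does not divide 24 h")
    temps = np.asarray(temps, dtype=float)
    if np.isnan(temps).any():
        raise MissingDataError("temperature gap inside the chilling window")
    in_band = (temps >= t_min) & (temps <= t_max)
    ch = float(in_band.sum() * step_hours)
    return ChillingSum(ch_sum=ch, hours_elapsed=temps.size * step_hours)


def day_length(latitude: float, doy: int | float) -> DayLength:
    """Day length (h) at a latitude and day-of-year, CBM model.

    The solar angle theta and declination-related angle phi are evaluated
    from the day-of-year, and day length follows from the sunrise equation
    with a 0.8333 degree horizon depression.  The inverse-cosine argument is
    clamped to [-1, 1], so polar day returns 24 h and polar night 0 h.
    """
    if not -90 <= latitude <= 90:
        raise InvalidParameterError(f"latitude {latitude} out of [-90, 90]")
    if not 1 <= doy <= 366:
        raise InvalidParameterError(f"day-of-year {doy} out of [1, 366]")
    theta = 0.2163108 + 2.0 * math.atan(
        0.9671396 * math.tan(0.0086 * (float(doy) - 186.0))
    )
    phi = math.asin(_CBM_SIN_OBLIQUITY * math.cos(theta))
    lat_rad = math.radians(latitude)
    numerator = math.sin(math.radians(_CBM_P_DEG)) + math.sin(lat_rad) * math.sin(phi)
    denominator = math.cos(lat_rad) * math.cos(phi)
    arg = numerator / denominator
    arg = min(1.0, max(-1.0, arg))
    hours = 24.0 - (24.0 / math.pi) * math.acos(arg)
    return DayLength(
        hours=hours,
        latitude=latitude,
        doy=int(doy),
        declination_rad=phi,
        solar_angle_rad=theta,
    )


def day_length_hours(latitude: float, doys: np.ndarray) -> np.ndarray:
    """Vectorized day length (h) over an array of day-of-year values."""
    doys = np.asarray(doys, dtype=float)
    if not -90 <= latitude <= 90:
        raise InvalidParameterError(f"latitude {latitude} out of [-90, 90]")
    if ((doys < 1) | (doys > 366)).any():
        raise InvalidParameterError("day-of-year out of [1, 366]")
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.0086 * (doys - 186.0)))
    phi = np.arcsin(_CBM_SIN_OBLIQUITY * np.cos(theta))
    lat_rad = math.radians(latitude)
    arg = (np.sin(math.radians(_CBM_P_DEG)) + np.sin(lat_rad) * np.sin(phi)) / (
        np.cos(lat_rad) * np.cos(phi)
    )
    return 24.0 - (24.0 / np.pi) * np.arccos(np.clip(arg, -1.0, 1.0))


def preseason_temperature(
    temps: np.ndarray,
    mean_event_doy: int,
    window: int = 60,
) -> float:
    """Mean temperature over the ``window`` days preceding the event day.

    The window is right-open: it covers DOY ``mean_event_doy - window``
    through ``mean_event_doy - 1``, excluding the event day itself.
    """
    temps = np.asarray(temps, dtype=float)
    if window < 1:
        raise InvalidParameterError("window must be at least 1 day")
    start = mean_event_doy - window
    if start < 1:
        raise MissingDataError(
            f"{window}-day window before DOY {mean_event_doy} starts before the series"
        )
    if mean_event_doy - 1 > temps.size:
        raise MissingDataError("series does not cover the preseason window")
    segment = temps[start - 1 : mean_event_doy - 1]
    if np.isnan(segment).any():
        raise MissingDataError("temperature gap inside the preseason window")
    return float(segment.mean())


def forcing_fulfilment_doy(
    temps: np.ndarray,
    requirement: float,
    start_doy: int = 1,
    base: float = BASE_TEMP_C,
) -> int | None:
    """Smallest DOY at which accumulated degree-days reach a requirement.

    Accumulation starts at ``start_doy`` (default 1 January).  Returns
    ``None`` when the requirement is never reached within the series — a
    missing flag, not an error.
    """
    if requirement <= 0:
        raise InvalidParameterError("forcing requirement must be positive")
    temps = np.asarray(temps, dtype=float)
    increments = np.clip(temps[start_doy - 1 :] - base, 0.0, None)
    cum = np.cumsum(increments)
    idx = int(np.searchsorted(cum, requirement, side="left"))
    if idx >= cum.size or cum[idx] < requirement:
        return None
    return start_doy + idx
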