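"""Shared fixtures: tiny deterministic climates and record tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenosync import climate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def constant_climate():
    """Six years of constant 15 degC (10 DD/day above the 5 degC base)."""
    return climate.ClimateSeries(
        daily=np.full((6, 365), 15.0), start_year=2000, latitude=48.5
    )


@pytest.fixture
def seasonal_climate():
    """Deterministic seasonal cycle, no noise, 22 years."""
    params = climate.ClimateParams(
        noise_sd=0.0, year_offsets_sd=0.0, warming_trend=0.0, n_years=22, seed=0
    )
    return climate.generate_temperature_series(params)


def make_records(entries):
    """Build a record table from (series_id, lat, lon, alt, year, doy) tuples."""
    return pd.DataFrame(
        [
            {
                "series_id": sid,
                "species": "Fagus sylvatica",
                "phase": "leafout_BBCH11",
                "lat": lat,
                "lon": lon,
                "alt_m": alt,
                "year": year,
                "doy": doy,
            }
            for sid, lat, lon, alt, year, doy in entries
        ]
    )


@pytest.fixture
def toy_panel():
    """A hand-built 3-individual x 4-year panel on a known grid."""
    from phenosync.cleaning import PixelPanel

    dates = np.array(
        [
            [100.0, 102.0, 104.0, 100.0],
            [102.0, 102.0, 106.0, 101.0],
            [104.0, 102.0, 108.0, 102.0],
        ]
    )
    return PixelPanel(
        pixel=(48, 11),
        species="Fagus sylvatica",
        phase="leafout_BBCH11",
        individuals=["a", "b", "c"],
        years=np.array([2001, 2002, 2003, 2004]),
        dates=dates,
        altitudes=np.array([500.0, 510.0, 520.0]),
        latitude=48.5,
        longitude=11.5,
    )
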