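"""Cleaning and pixelization of PEP-style phenological observation tables.

A record table is a tidy :class:`pandas.DataFrame` with columns
``series_id, species, phase, lat, lon, alt_m, year, doy`` (one row per
observation; time series are treated as individuals).  The full chain,
in fixed order, is:

1. drop series whose across-year SD of event dates exceeds 25 days;
2. drop observations deviating from the series median by more than
   3 x MAD (unscaled median absolute deviation);
3. assign 1-degree pixels by flooring coordinates;
4. build per (pixel, species, phase) panels keeping the largest
   individual set sharing at least 15 common years (>= 3 individuals);
5. drop individuals more than 200 m from the panel's mean altitude;
6. drop years with less than 90% of individuals observed.

All thresholds follow strict/non-strict inequalities exactly as the
rules are stated: SD strictly greater than 25 drops, altitude deviation
strictly greater than 200 m drops, coverage of at least 90% keeps.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["series_id", "species", "phase", "lat", "lon", "alt_m", "year", "doy"]

PHASES = {"leafout_BBCH11", "leafout_BBCH10", "flowering_BBCH60"}

#: Above this exhaustive subset search is replaced by greedy elimination.
_EXHAUSTIVE_LIMIT = 15


def read_records(path) -> pd.DataFrame:
    """Read a PEP-style observation CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table missing columns {missing}")
    df = df[RECORD_COLUMNS].copy()
    df["year"] = df["year"].astype(int)
    df["doy"] = df["doy"].astype(int)
    if ((df["doy"] < 1) | (df["doy"] > 366)).any():
        raise ValueError("doy outside [1, 366]")
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def filter_series_sd(records: pd.DataFrame, threshold: float = 25.0) -> pd.DataFrame:
    """Drop every series whose across-year sample SD of doy exceeds ``threshold``.

    Series with fewer than two years have undefined SD and are kept (they
    cannot survive the shared-years panel requirement anyway).
    """
    sd = records.groupby("series_id")["doy"].std(ddof=1)
    drop = set(sd.index[sd > threshold])
    return records[~records["series_id"].isin(drop)].reset_index(drop=True)


def filter_mad_outliers(records: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Drop observations deviating from their series median by more than k x MAD.

    MAD is the unscaled median absolute deviation.  When MAD is zero the
    rule degenerates: any observation off the median is dropped.
    """

    def _keep(group: pd.Series) -> pd.Series:
        med = group.median()
        dev = (group - med).abs()
        mad = dev.median()
        return dev <= k * mad

    mask = records.groupby("series_id")["doy"].transform(_keep)
    return records[mask.astype(bool)].reset_index(drop=True)


def assign_pixels(records: pd.DataFrame) -> pd.DataFrame:
    """Attach 1-degree pixel indices: floor of latitude and longitude."""
    out = records.copy()
    out["pixel_lat"] = np.floor(out["lat"]).astype(int)
    out["pixel_lon"] = np.floor(out["lon"]).astype(int)
    return out


@dataclass
class PixelPanel:
    """Individuals x years matrix of event dates for one pixel/species/phase."""

    pixel: tuple[int, int]
    species: str
    phase: str
    individuals: list[str]
    years: np.ndarray
    dates: np.ndarray  # (n_individuals, n_years), NaN = missing
    altitudes: np.ndarray
    latitude: float
    longitude: float

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def shared_years(self) -> int:
        """Number of years in which every individual has an observation."""
        if self.dates.size == 0:
            return 0
        return int((~np.isnan(self.dates)).all(axis=0).sum())

    def coverage(self) -> np.ndarray:
        """Per-year fraction of individuals observed."""
        return (~np.isnan(self.dates)).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dates, index=self.individuals, columns=self.years)

    def meta(self) -> dict:
        return {
            "pixel": list(self.pixel),
            "species": self.species,
            "phase": self.phase,
            "n_individuals": self.n_individuals,
            "years": [int(y) for y in self.years],
            "individuals": list(self.individuals),
            "altitudes": [float(a) for a in self.altitudes],
            "latitude": self.latitude,
            "longitude": self.longitude,
        }


def _select_individuals(
    avail: np.ndarray, min_individuals: int, min_shared_years: int
) -> list[int] | None:
    """Largest individual subset whose common-year count meets the threshold.

    ``avail`` is a boolean (individuals x years) presence matrix.  Small
    panels are searched exhaustively (size-descending, ties broken by the
    larger common-year count); larger ones by greedy elimination of the
    individual whose removal most increases the common-year count.
    """
    n = avail.shape[0]
    if n < min_individuals:
        return None
    masks = [_bitmask(row) for row in avail]
    full = (1 << avail.shape[1]) - 1

    def common(subset) -> int:
        m = full
        for i in subset:
            m &= masks[i]
        return m.bit_count()

    if n <= _EXHAUSTIVE_LIMIT:
        for size in range(n, min_individuals - 1, -1):
            best, best_common = None, -1
            for combo in itertools.combinations(range(n), size):
                c = common(combo)
                if c >= min_shared_years and c > best_common:
                    best, best_common = combo, c
            if best is not None:
                return list(best)
        return None

    keep = list(range(n))
    while len(keep) > min_individuals and common(keep) < min_shared_years:
        scores = [(common([j for j in keep if j != i]), i) for i in keep]
        _, worst = max(scores)
        keep.remove(worst)
    if len(keep) >= min_individuals and common(keep) >= min_shared_years:
        return keep
    return None


def _bitmask(row: np.ndarray) -> int:
    m = 0
    for j, v in enumerate(row):
        if v:
            m |= 1 << j
    return m


def build_panels(
    records: pd.DataFrame,
    min_individuals: int = 3,
    min_shared_years: int = 15,
) -> list[PixelPanel]:
    """Group pixelized records into panels meeting the shared-year rule.

    Per (pixel, species, phase), retains the largest set of individuals
    that all have data for at least ``min_shared_years`` common years;
    groups where no such set of ``min_individuals`` exists yield no panel.
    The panel keeps every year in which at least one retained individual
    was observed (the coverage filter prunes years later).
    """
    panels: list[PixelPanel] = []
    keys = ["pixel_lat", "pixel_lon", "species", "phase"]
    for (plat, plon, species, phase), group in records.groupby(keys, sort=True):
        pivot = group.pivot_table(index="series_id", columns="year", values="doy")
        pivot = pivot.sort_index()
        avail = pivot.notna().to_numpy()
        sel = _select_individuals(avail, min_individuals, min_shared_years)
        if sel is None:
            continue
        inds = [pivot.index[i] for i in sorted(sel)]
        sub = pivot.loc[inds]
        year_mask = sub.notna().any(axis=0)
        sub = sub.loc[:, year_mask]
        alt = group.groupby("series_id")["alt_m"].mean().loc[inds].to_numpy()
        panels.append(
            PixelPanel(
                pixel=(int(plat), int(plon)),
                species=species,
                phase=phase,
                individuals=list(inds),
                years=sub.columns.to_numpy(dtype=int),
                dates=sub.to_numpy(dtype=float),
                altitudes=alt,
                latitude=float(group["lat"].mean()),
                longitude=float(group["lon"].mean()),
            )
        )
    return panels


def filter_altitude(panel: PixelPanel, max_dev: float = 200.0) -> PixelPanel:
    """Drop individuals deviating more than ``max_dev`` m from the mean altitude.

    A single pass: the mean is computed once over all current individuals.
    """
    mean_alt = panel.altitudes.mean()
    keep = np.abs(panel.altitudes - mean_alt) <= max_dev
    return replace(
        panel,
        individuals=[ind for ind, k in zip(panel.individuals, keep) if k],
        dates=panel.dates[keep],
        altitudes=panel.altitudes[keep],
    )


def filter_coverage(panel: PixelPanel, min_coverage: float = 0.90) -> PixelPanel:
    """Drop years observed for less than ``min_coverage`` of individuals."""
    if panel.n_individuals == 0:
        return panel
    keep = panel.coverage() >= min_coverage
    return replace(panel, years=panel.years[keep], dates=panel.dates[:, keep])


def panel_is_valid(
    panel: PixelPanel, min_individuals: int = 3, min_shared_years: int = 15
) -> bool:
    return (
        panel.n_individuals >= min_individuals
        and panel.shared_years() >= min_shared_years
    )


def clean_pipeline(
    records: pd.DataFrame,
    sd_threshold: float = 25.0,
    mad_k: float = 3.0,
    min_individuals: int = 3,
    min_shared_years: int = 15,
    max_altitude_dev: float = 200.0,
    min_coverage: float = 0.90,
) -> tuple[list[PixelPanel], dict]:
    """Run the full cleaning chain and return panels plus a filter ledger.

    The ledger counts what each rule removed, so a run can be audited:
    ``series_sd_removed`` (observations), ``mad_removed`` (observations),
    ``panels_built``, ``altitude_removed`` (individuals),
    ``coverage_removed`` (panel-years), ``panels_final``.
    """
    ledger: dict[str, int] = {"records_in": len(records)}
    step = filter_series_sd(records, sd_threshold)
    ledger["series_sd_removed"] = len(records) - len(step)
    after_mad = filter_mad_outliers(step, mad_k)
    ledger["mad_removed"] = len(step) - len(after_mad)
    pixelized = assign_pixels(after_mad)
    panels = build_panels(pixelized, min_individuals, min_shared_years)
    ledger["panels_built"] = len(panels)
    ledger["altitude_removed"] = 0
    ledger["coverage_removed"] = 0
    final: list[PixelPanel] = []
    for panel in panels:
        trimmed = filter_altitude(panel, max_altitude_dev)
        ledger["altitude_removed"] += panel.n_individuals - trimmed.n_individuals
        covered = filter_coverage(trimmed, min_coverage)
        ledger["coverage_removed"] += len(trimmed.years) - len(covered.years)
        if panel_is_valid(covered, min_individuals, min_shared_years):
            final.append(covered)
    ledger["panels_final"] = len(final)
    return final, ledger


def export_panel(panel: PixelPanel, stem: Path) -> None:
    """Write a panel as a wide CSV plus a JSON metadata sidecar."""
    stem = Path(stem)
    panel.to_frame().to_csv(stem.with_suffix(".csv"))
    stem.with_suffix(".json").write_text(json.dumps(panel.meta(), indent=2))
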