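"""End-to-end orchestration of the synthetic synchrony analysis.

``run_all`` wires the stages together — synthetic climate and phenology,
PEP-style cleaning, per-pixel synchrony series, per-pixel regressions and
their cross-pixel summary, the Bayesian distribution model, and
optionally the degree-day null and the twig experiment — writing every
intermediate artifact plus an auditable log (seeds, filter ledger, stage
outcomes) into a run directory.

A single global seed is split deterministically per stage and per pixel
with :class:`numpy.random.SeedSequence`, so a run is a pure function of
its configuration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cleaning, climate, ddnull, hbayes, synchrony, twiglab
from .exceptions import DegenerateInputError, PhenosyncError


@dataclass
class RunConfig:
    """Configuration of a full run.

    ``pixel_latitudes`` positions one population per 1-degree pixel; all
    other knobs mirror the stage parameters they are forwarded to.
    """

    seed: int = 0
    out_dir: str = "phenosync_run"
    n_years: int = 22
    n_individuals: int = 12
    pixel_latitudes: tuple[float, ...] = (46.5, 47.5, 48.5, 49.5, 50.5)
    climate: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    min_individuals: int = 3
    min_shared_years: int = 15
    run_ddnull: bool = True
    run_twiglab: bool = True
    hb_iterations: int = 4000
    hb_burnin: int = 1000
    hb_chains: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PhenosyncError(f"unknown config keys: {sorted(unknown)}")
        if "pixel_latitudes" in raw:
            raw["pixel_latitudes"] = tuple(raw["pixel_latitudes"])
        return cls(**raw)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_all(config: RunConfig) -> Path:
    """Execute the pipeline and return the run directory.

    Raises :class:`PhenosyncError` naming the failing stage on any stage
    error; a run that produces zero panels exits cleanly with a
    ``no-data`` marker in the summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"seed={config.seed}"]
    summary: dict = {"seed": config.seed}

    n_pix = len(config.pixel_latitudes)
    seeds = _stage_seeds(config.seed, 2 * n_pix + 3)
    pixel_seeds, pop_seeds = seeds[:n_pix], seeds[n_pix : 2 * n_pix]
    dd_seed, twig_seed, hb_seed = seeds[2 * n_pix :]

    # --- synthetic climate and phenology, one population per pixel ---
    stage = "synthclim"
    try:
        climates: dict[tuple[int, int], climate.ClimateSeries] = {}
        records = []
        for lat, cseed, pseed in zip(config.pixel_latitudes, pixel_seeds, pop_seeds):
            lon = 11.5
            cparams = climate.ClimateParams(
                n_years=config.n_years,
                seed=cseed,
                latitude=lat,
                longitude=lon,
                **config.climate,
            )
            series = climate.generate_temperature_series(cparams)
            spec = climate.PopulationSpec(
                n_individuals=config.n_individuals,
                latitude=lat,
                longitude=lon,
                seed=pseed,
                **config.population,
            )
            events = climate.simulate_population(spec, series)
            records.append(events)
            climates[(int(np.floor(lat)), int(np.floor(lon)))] = series
        events = pd.concat(records, ignore_index=True)
        written = climate.emit_records(events, out / "records.csv")
        log.append(f"synthclim: {len(written)} observations written")
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PhenosyncError(f"stage {stage} failed: {exc}") from exc

    # --- cleaning ---
    stage = "pepclean"
    try:
        raw = cleaning.read_records(out / "records.csv")
        panels, ledger = cleaning.clean_pipeline(
            raw,
            min_individuals=config.min_individuals,
            min_shared_years=config.min_shared_years,
        )
        log.append(f"pepclean ledger: {ledger}")
        summary["filter_ledger"] = ledger
    except Exception as exc:  # noqa: BLE001
        raise PhenosyncError(f"stage {stage} failed: {exc}") from exc

    if not panels:
        summary["status"] = "no-data"
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        (out / "log.txt").write_text("\n".join(log + ["no panels survived cleaning"]))
        return out

    # --- synchrony ---
    stage = "synchrony"
    try:
        tables = []
        regressions = []
        for panel in panels:
            series = climates[panel.pixel]
            table = synchrony.compute_synchrony(panel, series)
            table = table.assign(
                pixel=f"{panel.pixel[0]}_{panel.pixel[1]}", species=panel.species
            )
            tables.append(table)
            try:
                regressions.append(synchrony.pixel_regression(table))
            except DegenerateInputError as exc:
                log.append(f"pixel {panel.pixel} regression skipped: {exc}")
        tidy = pd.concat(tables).reset_index()
        tidy.to_csv(out / "synchrony.csv", index=False)
        synchrony.regressions_to_frame(regressions).to_csv(
            out / "regressions.csv", index=False
        )
        if len(regressions) >= 2:
            corr = synchrony.summarize_correlations(regressions)
            summary["correlations"] = dataclasses.asdict(corr)
        summary["n_panels"] = len(panels)
    except PhenosyncError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PhenosyncError(f"stage {stage} failed: {exc}") from exc

    # --- hierarchical Bayesian model (temperature variant) ---
    stage = "hbayes"
    try:
        data = hbayes.HBData.from_frame(
            tidy.dropna(subset=["los", "preseason_temp"]),
            response="los",
            predictors=["preseason_temp"],
            species_col="species",
            pixel_col="pixel",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = hbayes.fit_hb_model(
                data,
                chains=config.hb_chains,
                iterations=config.hb_iterations,
                burnin=config.hb_burnin,
                seed=hb_seed,
            )
        hb_summary = post.summary()
        hb_summary.to_csv(out / "hbayes_summary.csv")
        summary["hbayes"] = {
            "beta_preseason_temp": float(hb_summary.loc["beta[preseason_temp]", "mean"]),
            "converged": bool(post.converged),
        }
        log.append(f"hbayes converged={post.converged}")
    except Exception as exc:  # noqa: BLE001
        raise PhenosyncError(f"stage {stage} failed: {exc}") from exc

    # --- degree-day-only null ---
    if config.run_ddnull:
        stage = "ddnull"
        try:
            series = next(iter(climates.values()))
            result = ddnull.simulate_dd_only(ddnull.DDNullConfig(seed=dd_seed), series)
            result.to_frame().to_csv(out / "ddnull.csv")
            summary["ddnull_slope"] = None if result.degenerate else result.slope
        except Exception as exc:  # noqa: BLE001
            raise PhenosyncError(f"stage {stage} failed: {exc}") from exc

    # --- twig experiment ---
    if config.run_twiglab:
        stage = "twiglab"
        try:
            nested = twiglab.simulate_nested_twigs(seed=twig_seed)
            comps = twiglab.variance_components(nested)
            summary["twig_variance_shares"] = comps.shares
        except Exception as exc:  # noqa: BLE001
            raise PhenosyncError(f"stage {stage} failed: {exc}") from exc

    summary["status"] = "ok"
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out / "log.txt").write_text("\n".join(log))
    return out
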