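"""Run configuration, seed fan-out, fixtures and pipeline orchestration.

A single YAML file (all keys optional, unknown keys rejected) describes a
complete run: climate profile, scenario grid, thermal staging constants,
phenology calendar, split and model settings. One global seed fans out
deterministically to per-stage seeds through a name-keyed counter scheme,
so any stage can be rerun in isolation and reproduce its stream.
"""

from __future__ import annotations

import datetime as dt
import logging
import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import cropsim, experiment, features, models, phasing, weather
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "stage_seed",
    "make_fixture",
    "FixtureBundle",
    "run_pipeline",
]


class _Schema(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClimateSection(_Schema):
    latitude: float = 36.5
    annual_tmean_target: float = 12.5
    annual_precip_target: float = 700.0
    temp_seasonal_amplitude: float = 14.5
    temp_ar1_coeff: float = 0.70
    temp_noise_sd: float = 2.0
    diurnal_range_mean: float = 9.0
    wet_day_prob_wet: float = 0.45
    wet_day_prob_dry: float = 0.22
    rain_gamma_shape: float = 1.0
    rain_gamma_scale: float = 5.9
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50


class GridSection(_Schema):
    tsum1_steps: list[float] = [800.0, 900.0, 1000.0]
    tsum2_steps: list[float] = [750.0, 850.0, 950.0]
    slatb1_steps: list[float] = [0.0026, 0.00305, 0.0035]
    span_steps: list[float] = [40.0]
    tbase_leafage_steps: list[float] = [9.0]
    soils: list[str] = ["sandy_loam", "light_loam", "medium_loam"]
    sowing_dates: list[str] = ["06-01", "06-10", "06-19"]
    water_modes: list[str] = ["potential", "water_limited"]


class ThermalSection(_Schema):
    tbase: float = 8.0
    tmax_cap: float = 29.0


class CalendarSection(_Schema):
    emergence: str = "06-25"
    jointing: str = "07-15"
    flowering: str = "08-05"
    milk_maturity: str = "08-25"
    maturity: str = "09-15"


class SplitSection(_Schema):
    train_fraction: float = 0.9
    grouping: str = "random"


class TreeSection(_Schema):
    n_estimators_grid: list[int] = [100, 300]
    max_depth_grid: list[int | None] = [8, 16, None]
    max_features_grid: list[float | str] = ["sqrt", 1 / 3, 1.0]
    cv_folds: int = 5


class RecurrentSection(_Schema):
    n_layers: int = 2
    units: int = 64
    dense_units: int = 32
    epochs: int = 500
    batch_size: int = 128
    dropout: float = 0.1
    learning_rate: float = 2.5e-3
    val_fraction: float = 0.1
    patience: int = 60
    lr_plateau: int = 20
    min_learning_rate: float = 1e-4


class DesignSection(_Schema):
    phase_combos: list[str] = list(experiment.PHASE_COMBOS)
    feature_sets: list[str] = list(experiment.FEATURE_SETS)
    models: list[str] = ["tree_ensemble", "recurrent"]
    recurrent_singles: bool = False
    importance_repeats: int = 10


#: Upper bound on the desk-scale ensemble size.
DESK_SCALE_MAX_SCENARIOS = 20_000


class RunConfig(_Schema):
    """Fully validated run configuration with all defaults filled."""

    seed: int = 0
    out_dir: str = "runs"
    scale: str = "desk"
    n_sites: int = 1
    n_years: int = 21
    start_year: int = 1995
    season_cutoff_days: int = 130
    climate: ClimateSection = ClimateSection()
    grid: GridSection = GridSection()
    thermal: ThermalSection = ThermalSection()
    calendar: CalendarSection = CalendarSection()
    split: SplitSection = SplitSection()
    tree: TreeSection = TreeSection()
    recurrent: RecurrentSection = RecurrentSection()
    design: DesignSection = DesignSection()

    # ---- builders to the runtime dataclasses -------------------------------

    def climate_profile(self, seed: int | None = None) -> weather.ClimateProfile:
        return weather.ClimateProfile(
            **self.climate.model_dump(),
            seed=stage_seed(self.seed, "weather") if seed is None else seed,
        )

    def thermal_config(self) -> phasing.ThermalConfig:
        return phasing.ThermalConfig(**self.thermal.model_dump())

    def phenology_calendar(self) -> phasing.PhenologyCalendar:
        return phasing.PhenologyCalendar(**self.calendar.model_dump())

    def grid_spec(self, site_years) -> cropsim.GridSpec:
        d = self.grid.model_dump()
        spec = cropsim.GridSpec(
            **{k: tuple(v) for k, v in d.items()}, site_years=list(site_years)
        )
        if self.scale == "desk" and spec.size() > DESK_SCALE_MAX_SCENARIOS:
            raise ConfigurationError(
                f"desk-scale ensemble of {spec.size()} scenarios exceeds "
                f"{DESK_SCALE_MAX_SCENARIOS}"
            )
        return spec

    def split_spec(self) -> models.SplitSpec:
        return models.SplitSpec(
            **self.split.model_dump(), seed=stage_seed(self.seed, "split")
        )

    def tree_config(self) -> models.TreeEnsembleConfig:
        d = self.tree.model_dump()
        return models.TreeEnsembleConfig(
            n_estimators_grid=tuple(d["n_estimators_grid"]),
            max_depth_grid=tuple(d["max_depth_grid"]),
            max_features_grid=tuple(d["max_features_grid"]),
            cv_folds=d["cv_folds"],
            seed=stage_seed(self.seed, "tree"),
        )

    def recurrent_config(self) -> models.RecurrentNetConfig:
        return models.RecurrentNetConfig(
            **self.recurrent.model_dump(), seed=stage_seed(self.seed, "recurrent")
        )

    def experiment_design(self) -> experiment.ExperimentDesign:
        d = self.design.model_dump()
        return experiment.ExperimentDesign(
            phase_combos=d["phase_combos"],
            feature_sets=d["feature_sets"],
            models=d["models"],
            recurrent_singles=d["recurrent_singles"],
            importance_repeats=d["importance_repeats"],
            split=self.split_spec(),
            tree_config=self.tree_config(),
            recurrent_config=self.recurrent_config(),
        )


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``None`` or an empty file yields the all-defaults configuration;
    unknown keys and constraint violations raise a configuration error
    naming the key.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigurationError(f"invalid config key '{loc}': {first['msg']}") from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, keyed by stage name."""
    return int(
        np.random.SeedSequence(
            entropy=int(global_seed) % (2**31),
            spawn_key=(zlib.crc32(stage.encode()),),
        ).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# Fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Miniature end-to-end ensemble for tests and smoke runs."""

    weather: weather.WeatherSeries
    thresholds: phasing.ThermalThresholds
    scenarios: list
    traces: list
    bounds: list
    matrix: features.PhaseFeatureMatrix


def make_fixture(seed: int = 0, n_years: int = 2) -> FixtureBundle:
    """Seconds-scale deterministic fixture exercising every pipeline stage
    (≤ 50 scenarios over two synthetic years)."""
    profile = weather.ClimateProfile(seed=stage_seed(seed, "weather"))
    series = weather.generate_weather(profile, n_years=n_years,
                                      seed=stage_seed(seed, "weather"))
    thresholds = phasing.calibrate_thresholds([series])
    grid = cropsim.GridSpec(
        tsum1_steps=(850.0, 950.0),
        tsum2_steps=(800.0,),
        slatb1_steps=(0.003,),
        soils=("sandy_loam", "medium_loam"),
        sowing_dates=("06-01", "06-19"),
        site_years=[(series, y) for y in series.years],
    )
    scenarios = cropsim.build_scenario_grid(grid)
    traces = cropsim.run_ensemble(scenarios)
    bounds = [phasing.segment_trace(t, thresholds) for t in traces]
    matrix = features.build_feature_matrix(scenarios, traces, bounds)
    return FixtureBundle(weather=series, thresholds=thresholds,
                         scenarios=scenarios, traces=traces, bounds=bounds,
                         matrix=matrix)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig, outdir=None, workers: int = 1) -> dict:
    """Execute the full study: weather → simulation → staging → features →
    design. Returns the in-memory artifacts; writes CSVs when ``outdir``."""
    t0 = time.time()
    thermal = cfg.thermal_config()
    calendar = cfg.phenology_calendar()

    sites = []
    for i in range(cfg.n_sites):
        profile = cfg.climate_profile(seed=stage_seed(cfg.seed, f"weather-{i}"))
        sites.append(weather.generate_weather(
            profile, n_years=cfg.n_years, seed=profile.seed,
            start_year=cfg.start_year, site_id=f"site{i:02d}",
        ))
    logger.info("generated %d site(s) x %d years in %.1fs",
                cfg.n_sites, cfg.n_years, time.time() - t0)

    thresholds = phasing.calibrate_thresholds(sites, calendar, thermal)
    site_years = [(s, y) for s in sites for y in s.years]
    grid = cfg.grid_spec(site_years)
    scenarios = cropsim.build_scenario_grid(grid)
    t1 = time.time()
    traces = cropsim.run_ensemble(scenarios, workers=workers, thermal=thermal,
                                  season_cutoff_days=cfg.season_cutoff_days)
    logger.info("simulated %d scenarios in %.1fs", len(scenarios), time.time() - t1)

    bounds = [phasing.segment_trace(t, thresholds, thermal) for t in traces]
    validation = phasing.validate_stage_dvs(traces, bounds)
    matrix = features.build_feature_matrix(scenarios, traces, bounds)

    design = cfg.experiment_design()
    t2 = time.time()
    report = experiment.run_design(matrix, design)
    logger.info("evaluated %d design cells in %.1fs", len(report.rows),
                time.time() - t2)

    artifacts = {
        "sites": sites,
        "thresholds": thresholds,
        "scenarios": scenarios,
        "traces": traces,
        "bounds": bounds,
        "dvs_validation": validation,
        "matrix": matrix,
        "report": report,
    }
    if outdir is not None:
        write_artifacts(artifacts, outdir)
    return artifacts


# ---------------------------------------------------------------------------
# Artifact serialization (plain CSV, documented schemas)
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["scenario_id", "date", "dvs", "lai", "tra", "sm", "w_leaf",
                 "w_stem", "w_storage", "w_root", "stress", "tmean", "tmax",
                 "rain"]


def traces_to_frame(traces) -> pd.DataFrame:
    """Combined long-format daily trace table."""
    parts = []
    for t in traces:
        if len(t) == 0:
            continue
        parts.append(pd.DataFrame({
            "scenario_id": t.scenario_id,
            "date": [d.isoformat() for d in t.dates],
            "dvs": t.dvs, "lai": t.lai, "tra": t.tra, "sm": t.sm,
            "w_leaf": t.w_leaf, "w_stem": t.w_stem, "w_storage": t.w_storage,
            "w_root": t.w_root, "stress": t.stress, "tmean": t.tmean,
            "tmax": t.tmax, "rain": t.rain,
        }))
    if not parts:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(parts, ignore_index=True)[TRACE_COLUMNS]


def traces_from_frame(frame: pd.DataFrame, summary: pd.DataFrame):
    """Rebuild simulation traces from the long table + ensemble summary."""
    flags = summary.set_index("scenario_id")
    traces = []
    z = np.empty(0)
    for sid in flags.index:
        g = frame[frame["scenario_id"] == sid]
        row = flags.loc[sid]
        if len(g) == 0:
            traces.append(cropsim.SimulationTrace(
                scenario_id=sid, dates=np.empty(0, dtype=object), dvs=z, lai=z,
                tra=z, sm=z, w_leaf=z, w_stem=z, w_storage=z, w_root=z,
                stress=z, tmean=z, tmax=z, rain=z, irrigation=z, soil_evap=z,
                drainage=z, storage_mm=z, yield_final=float(row["yield_final"]),
                immature=bool(row["immature"]), mature=bool(row["mature"]),
            ))
            continue
        dates = np.array([dt.date.fromisoformat(d) for d in g["date"]],
                         dtype=object)
        n = len(g)
        traces.append(cropsim.SimulationTrace(
            scenario_id=sid, dates=dates,
            **{c: g[c].to_numpy(float) for c in TRACE_COLUMNS[2:]},
            irrigation=np.zeros(n), soil_evap=np.zeros(n),
            drainage=np.zeros(n), storage_mm=np.zeros(n),
            yield_final=float(row["yield_final"]),
            immature=bool(row["immature"]), mature=bool(row["mature"]),
            emergence_date=dates[0],
        ))
    return traces


def summary_frame(scenarios, traces) -> pd.DataFrame:
    rows = []
    for s, t in zip(scenarios, traces):
        row = {"scenario_id": s.scenario_id}
        row.update(s.levels)
        row.update({"yield_final": t.yield_final, "mature": t.mature,
                    "immature": t.immature})
        rows.append(row)
    return pd.DataFrame(rows)


def thresholds_frame(th: phasing.ThermalThresholds) -> pd.DataFrame:
    return pd.DataFrame({
        "stage": phasing.STAGES,
        "te_threshold": [th.te_at_stage[s] for s in phasing.STAGES],
        "estimated_dvs": [th.estimated_dvs[s] for s in phasing.STAGES],
    })


def bounds_frame(bounds_list) -> pd.DataFrame:
    rows = []
    for b in bounds_list:
        for phase, (a, e) in b.bounds.items():
            dates = b.dates.get(phase)
            rows.append({
                "scenario_id": b.scenario_id, "phase": phase,
                "start_index": a, "end_index": e,
                "start_date": dates[0].isoformat() if dates else "",
                "end_date": dates[1].isoformat() if dates else "",
                "truncated": b.truncated,
            })
    return pd.DataFrame(rows)


def write_artifacts(artifacts: dict, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    for s in artifacts["sites"]:
        weather.write_weather(s, os.path.join(outdir, f"weather_{s.site_id}.csv"))
    thresholds_frame(artifacts["thresholds"]).to_csv(
        os.path.join(outdir, "thermal_thresholds.csv"), index=False)
    traces_to_frame(artifacts["traces"]).to_csv(
        os.path.join(outdir, "traces.csv"), index=False)
    summary_frame(artifacts["scenarios"], artifacts["traces"]).to_csv(
        os.path.join(outdir, "ensemble_summary.csv"), index=False)
    bounds_frame(artifacts["bounds"]).to_csv(
        os.path.join(outdir, "phase_bounds.csv"), index=False)
    artifacts["matrix"].frame.to_csv(
        os.path.join(outdir, "feature_matrix.csv"), index=False)
    experiment.render_report(artifacts["report"], outdir)
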