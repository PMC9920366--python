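"""Thermal-time phenology staging for summer maize.

Growth-stage boundaries are expressed as effective accumulated temperature
(growing degree days with a lower base and an upper cap):

    Te(T) = 0            for T <= Tbase
          = T - Tbase    for Tbase < T < Tmax
          = Tmax - Tbase for T >= Tmax

with Tbase = 8 °C and Tmax = 29 °C for maize development. A calendar of
empirical stage dates (emergence late June → jointing mid-July → flowering
early August → milk maturity late August → maturity mid-September) is
converted, year by year, into cumulative Te since emergence; the multi-year
mean is the thermal threshold of each stage. Simulated traces are segmented
into four growth phases (GP1 emergence→jointing, GP2 jointing→flowering,
GP3 flowering→milk maturity, GP4 milk maturity→maturity) at the first day
the trace's own cumulative Te reaches each threshold. Phase intervals are
half-open [start, end): the crossing day belongs to the later phase.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "ThermalConfig",
    "PhenologyCalendar",
    "ThermalThresholds",
    "GrowthPhaseBounds",
    "STAGES",
    "PHASES",
    "effective_daily_te",
    "cumulative_te",
    "calibrate_thresholds",
    "segment_trace",
    "validate_stage_dvs",
]

#: Phenological stages in season order; emergence anchors the accumulation.
STAGES = ["emergence", "jointing", "flowering", "milk_maturity", "maturity"]
#: The four growth phases delimited by consecutive stages.
PHASES = ["GP1", "GP2", "GP3", "GP4"]

#: Central pseudo-variety thermal requirements (midpoints of the ensemble
#: ranges 800–1000 and 750–950 °C·d) used to express thresholds as an
#: estimated development stage.
CENTRAL_TSUM1 = 900.0
CENTRAL_TSUM2 = 850.0


@dataclass(frozen=True)
class ThermalConfig:
    """Base and cap temperatures of the effective-temperature response."""

    tbase: float = 8.0
    tmax_cap: float = 29.0

    def __post_init__(self):
        if not self.tbase < self.tmax_cap:
            raise ConfigurationError("tbase must be below tmax_cap")


def effective_daily_te(t_mean, config: ThermalConfig = ThermalConfig()):
    """Daily effective temperature (°C·d): clamp(T − Tbase, 0, Tmax − Tbase).

    Continuous and nondecreasing in T; accepts scalars or arrays.
    """
    t = np.asarray(t_mean, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InputError("temperature must be finite")
    out = np.clip(t - config.tbase, 0.0, config.tmax_cap - config.tbase)
    return float(out) if out.ndim == 0 else out


def cumulative_te(t_mean, config: ThermalConfig = ThermalConfig()):
    """Running sum of daily effective temperature over a temperature series."""
    return np.cumsum(effective_daily_te(np.asarray(t_mean, float), config))


@dataclass(frozen=True)
class PhenologyCalendar:
    """Empirical month-day stage calendar (defaults: regional summer maize)."""

    emergence: str = "06-25"
    jointing: str = "07-15"
    flowering: str = "08-05"
    milk_maturity: str = "08-25"
    maturity: str = "09-15"

    def __post_init__(self):
        dates = [self.date_in_year(s, 2001) for s in STAGES]
        if any(b <= a for a, b in zip(dates[:-1], dates[1:])):
            raise ConfigurationError("calendar stage dates must be strictly increasing")

    def date_in_year(self, stage: str, year: int) -> dt.date:
        md = getattr(self, stage)
        month, day = (int(p) for p in md.split("-"))
        return dt.date(year, month, day)


@dataclass(frozen=True)
class ThermalThresholds:
    """Cumulative-Te thresholds (since emergence) and estimated DVS per stage."""

    te_at_stage: dict[str, float]
    estimated_dvs: dict[str, float]
    n_years: int = 0

    def __post_init__(self):
        vals = [self.te_at_stage[s] for s in STAGES]
        if any(b <= a for a, b in zip(vals[:-1], vals[1:])):
            raise ConfigurationError("stage thresholds must be strictly increasing")
        if self.estimated_dvs.get("emergence", 0.0) != 0.0:
            raise ConfigurationError("estimated_dvs at emergence must be 0")


@dataclass
class GrowthPhaseBounds:
    """Half-open phase index intervals [start, end) into a trace's day axis."""

    scenario_id: str
    bounds: dict[str, tuple[int, int]]  # phase -> (start, end) day indices
    dates: dict[str, tuple[dt.date, dt.date]] = field(default_factory=dict)
    truncated: bool = False  # a late threshold was never reached
    crossed: dict[str, bool] = field(default_factory=dict)  # stage -> crossing observed

    def __getitem__(self, phase: str) -> tuple[int, int]:
        return self.bounds[phase]


def map_te_to_dvs(te: float, tsum1: float = CENTRAL_TSUM1,
                  tsum2: float = CENTRAL_TSUM2) -> float:
    """Development stage implied by cumulative Te under a two-segment clock."""
    if te <= tsum1:
        return te / tsum1
    return min(2.0, 1.0 + (te - tsum1) / tsum2)


def calibrate_thresholds(weather_years, calendar: PhenologyCalendar = PhenologyCalendar(),
                         config: ThermalConfig = ThermalConfig(),
                         central_tsum1: float = CENTRAL_TSUM1,
                         central_tsum2: float = CENTRAL_TSUM2) -> ThermalThresholds:
    """Convert the calendar-day phenology to thermal thresholds.

    For every full calendar year in ``weather_years`` (one or more
    :class:`~maizephase.weather.WeatherSeries`), daily Te is accumulated over
    the half-open interval [emergence date, stage date); the across-year mean
    is the stage threshold. Requires at least two year samples.
    """
    if not isinstance(weather_years, (list, tuple)):
        weather_years = [weather_years]
    per_stage: dict[str, list[float]] = {s: [] for s in STAGES}
    n_years = 0
    for series in weather_years:
        years = series.years
        if not years:
            raise InputError(
                f"weather series {series.site_id} covers no full calendar year"
            )
        for year in years:
            start = calendar.date_in_year("emergence", year)
            end = calendar.date_in_year("maturity", year)
            if not series.covers(start, end):
                raise InputError(
                    f"weather series {series.site_id} does not cover "
                    f"emergence..maturity of {year}"
                )
            n_days = (end - start).days
            tmean = series.arrays(start, n_days + 1)["TMEAN"]
            cum = np.concatenate([[0.0], cumulative_te(tmean, config)])
            for stage in STAGES:
                offs = (calendar.date_in_year(stage, year) - start).days
                per_stage[stage].append(float(cum[offs]))
            n_years += 1
    if n_years < 2:
        raise InputError("threshold calibration needs at least two years of weather")
    te_at_stage = {s: float(np.mean(per_stage[s])) for s in STAGES}
    estimated = {
        s: (0.0 if s == "emergence"
            else map_te_to_dvs(te_at_stage[s], central_tsum1, central_tsum2))
        for s in STAGES
    }
    return ThermalThresholds(te_at_stage=te_at_stage, estimated_dvs=estimated,
                             n_years=n_years)


def _crossing_index(cum_excl: np.ndarray, threshold: float) -> int | None:
    """Smallest i with cumulative Te over [0, i) >= threshold, else None.

    ``cum_excl[i]`` must hold the sum over day indices [0, i).
    """
    hits = np.nonzero(cum_excl >= threshold - 1e-9)[0]
    return int(hits[0]) if len(hits) else None


def segment_trace(trace, thresholds: ThermalThresholds,
                  config: ThermalConfig = ThermalConfig()) -> GrowthPhaseBounds:
    """Segment a simulation trace into the four growth phases.

    Each stage boundary is the first day index i such that the trace's own
    cumulative Te over [emergence, i) reaches the stage threshold. GP4 ends
    at the maturity crossing or at the trace end, whichever comes first; a
    missing crossing marks the segmentation as truncated.
    """
    te = effective_daily_te(np.asarray(trace.tmean, float), config)
    # cum_excl[i] = Te summed over day indices [0, i)
    cum_excl = np.concatenate([[0.0], np.cumsum(te)])
    n = len(te)
    idx: dict[str, int | None] = {"emergence": 0}
    for stage in STAGES[1:]:
        idx[stage] = _crossing_index(cum_excl, thresholds.te_at_stage[stage])
    truncated = any(idx[s] is None for s in STAGES[1:])
    resolved: dict[str, int] = {}
    for stage in STAGES:
        resolved[stage] = n if idx[stage] is None else min(idx[stage], n)
    bounds = {
        "GP1": (resolved["emergence"], resolved["jointing"]),
        "GP2": (resolved["jointing"], resolved["flowering"]),
        "GP3": (resolved["flowering"], resolved["milk_maturity"]),
        "GP4": (resolved["milk_maturity"], resolved["maturity"]),
    }
    dates = {}
    for phase, (a, b) in bounds.items():
        if a < n and b > a:
            dates[phase] = (trace.dates[a], trace.dates[min(b, n) - 1])
    if any(b <= a for a, b in bounds.values()):
        truncated = True
    crossed = {s: idx[s] is not None for s in STAGES[1:]}
    return GrowthPhaseBounds(
        scenario_id=trace.scenario_id, bounds=bounds, dates=dates,
        truncated=truncated, crossed=crossed,
    )


def validate_stage_dvs(traces, bounds_list) -> dict:
    """Ensemble statistics of simulated DVS at the estimated stage boundaries.

    For each stage the simulated DVS just as the cumulative-Te threshold is
    crossed (the last day of the preceding phase) is collected; the report
    gives mean and range per stage and the mean relative error (percent) of
    flowering against its true DVS of 1 and of maturity against 2. Truncated
    traces are excluded from stages they never reach.
    """
    if len(traces) != len(bounds_list):
        raise InputError("one bounds object per trace is required")
    at_stage: dict[str, list[float]] = {s: [] for s in STAGES[1:]}
    stage_end_phase = {"jointing": "GP1", "flowering": "GP2",
                       "milk_maturity": "GP3", "maturity": "GP4"}
    for trace, bounds in zip(traces, bounds_list):
        n = len(trace.dvs)
        for stage, phase in stage_end_phase.items():
            start, end = bounds[phase]
            if end <= start or end > n:
                continue
            if bounds.crossed and not bounds.crossed.get(stage, True):
                continue  # threshold never reached: no crossing observed
            at_stage[stage].append(float(trace.dvs[min(end, n) - 1]))
    report: dict = {"per_stage": {}, "n_traces": len(traces)}
    for stage, vals in at_stage.items():
        if not vals:
            report["per_stage"][stage] = None
            continue
        arr = np.asarray(vals)
        report["per_stage"][stage] = {
            "mean_dvs": float(arr.mean()),
            "min_dvs": float(arr.min()),
            "max_dvs": float(arr.max()),
            "n": int(arr.size),
        }
    for stage, target in (("flowering", 1.0), ("maturity", 2.0)):
        vals = at_stage[stage]
        key = f"{stage}_rel_error_pct"
        report[key] = (
            float(np.mean(np.abs(np.asarray(vals) - target) / target) * 100.0)
            if vals else None
        )
    return report
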