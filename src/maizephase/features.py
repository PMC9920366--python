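"""Per-phase yield factors, feature matrix assembly and correlation screening.

Nine candidate yield factors are aggregated over each of the four growth
phases (half-open day intervals):

* growth state — LAI mean, LAI cumulative sum, LAI maximum, LAI growth rate
  (net change divided by phase length in days);
* water — cumulative transpiration (TRA-sum, mm), cumulative volumetric soil
  moisture (SM-sum, cm³/cm³·d), cumulative precipitation (PPT-sum, mm);
* temperature — cumulative daily mean and maximum temperature (°C·d, raw
  temperatures, not base-capped).

Screening computes the Pearson correlation of every (feature, phase) column
with final yield and keeps, per feature type, the feature with the highest
mean |r| across the four phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .phasing import PHASES, GrowthPhaseBounds

__all__ = [
    "FEATURES",
    "TYPE_GROUPS",
    "PhaseFeatureSet",
    "PhaseFeatureMatrix",
    "CorrelationReport",
    "extract_phase_features",
    "build_feature_matrix",
    "correlate",
    "select_optimal",
    "minmax_normalize",
]

FEATURES = [
    "lai_mean", "lai_sum", "lai_max", "lai_rate",
    "tra_sum", "sm_sum", "ppt_sum",
    "tmean_sum", "tmax_sum",
]

TYPE_GROUPS = {
    "growth_state": ["lai_mean", "lai_sum", "lai_max", "lai_rate"],
    "water": ["tra_sum", "sm_sum", "ppt_sum"],
    "temperature": ["tmean_sum", "tmax_sum"],
}

FACTOR_COLUMNS = ["site", "year", "tsum1", "tsum2", "slatb1", "span",
                  "tbase_leafage", "soil", "sowing_date", "water_mode"]


@dataclass
class PhaseFeatureSet:
    """values[(feature, phase)] for one scenario; flagged if a phase is empty."""

    scenario_id: str
    values: dict[tuple[str, str], float]
    flagged: bool = False

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]


def column_name(feature: str, phase: str) -> str:
    return f"{feature}_{phase}"


def extract_phase_features(trace, bounds: GrowthPhaseBounds,
                           weather=None) -> PhaseFeatureSet:
    """Aggregate the nine features over each half-open phase interval.

    Daily LAI/TRA/SM come from the trace; precipitation and temperatures
    come from ``weather`` when given (aligned by date) and otherwise from
    the meteorological record the trace carries.
    """
    n = len(trace)
    if weather is not None:
        if n:
            w = weather.arrays(trace.dates[0], n)
            rain, tmean, tmax = w["RAIN"], w["TMEAN"], w["TMAX"]
        else:
            rain = tmean = tmax = np.empty(0)
    else:
        rain, tmean, tmax = trace.rain, trace.tmean, trace.tmax
    values: dict[tuple[str, str], float] = {}
    flagged = False
    for phase in PHASES:
        a, b = bounds[phase]
        a, b = max(0, a), min(n, b)
        if b <= a:
            flagged = True
            for feat in FEATURES:
                values[(feat, phase)] = np.nan
            continue
        lai = trace.lai[a:b]
        days = b - a
        values[("lai_mean", phase)] = float(lai.mean())
        values[("lai_sum", phase)] = float(lai.sum())
        values[("lai_max", phase)] = float(lai.max())
        values[("lai_rate", phase)] = float((lai[-1] - lai[0]) / days)
        values[("tra_sum", phase)] = float(trace.tra[a:b].sum())
        values[("sm_sum", phase)] = float(trace.sm[a:b].sum())
        values[("ppt_sum", phase)] = float(rain[a:b].sum())
        values[("tmean_sum", phase)] = float(tmean[a:b].sum())
        values[("tmax_sum", phase)] = float(tmax[a:b].sum())
    return PhaseFeatureSet(scenario_id=trace.scenario_id, values=values,
                           flagged=flagged)


@dataclass
class PhaseFeatureMatrix:
    """Scenario rows × (9 features × 4 phases) + yield target + provenance."""

    frame: pd.DataFrame
    n_excluded: int = 0

    @property
    def feature_columns(self) -> list[str]:
        return [column_name(f, p) for f in FEATURES for p in PHASES]

    def columns_for(self, features: list[str], phases: list[str]) -> list[str]:
        return [column_name(f, p) for p in phases for f in features]

    def __len__(self) -> int:
        return len(self.frame)


def build_feature_matrix(scenarios, traces, bounds_list,
                         weather=None) -> PhaseFeatureMatrix:
    """Assemble the ensemble feature matrix.

    Immature traces and truncated segmentations are excluded and counted;
    complete rows contain no missing values.
    """
    if not (len(scenarios) == len(traces) == len(bounds_list)):
        raise InputError("scenarios, traces and bounds must align one-to-one")
    rows = []
    excluded = 0
    for scen, trace, bounds in zip(scenarios, traces, bounds_list):
        if trace.immature or bounds.truncated:
            excluded += 1
            continue
        fs = extract_phase_features(trace, bounds, weather)
        if fs.flagged or any(np.isnan(v) for v in fs.values.values()):
            excluded += 1
            continue
        row = {"scenario_id": scen.scenario_id}
        row.update(scen.levels)
        for (feat, phase), v in fs.values.items():
            row[column_name(feat, phase)] = v
        row["yield"] = trace.yield_final
        rows.append(row)
    frame = pd.DataFrame(rows)
    return PhaseFeatureMatrix(frame=frame, n_excluded=excluded)


@dataclass
class CorrelationReport:
    """Pearson correlations of every (feature, phase) column with yield."""

    r: dict[tuple[str, str], float]
    mean_r_per_feature: dict[str, float]
    selected: dict[str, str] = field(default_factory=dict)  # type -> feature

    def as_frame(self) -> pd.DataFrame:
        """Feature × phase table of r values (layout of a correlation heatmap)."""
        data = {
            phase: [self.r.get((f, phase), np.nan) for f in FEATURES]
            for phase in PHASES
        }
        frame = pd.DataFrame(data, index=FEATURES)
        frame["mean_r"] = [self.mean_r_per_feature.get(f, np.nan) for f in FEATURES]
        return frame


def correlate(matrix: PhaseFeatureMatrix) -> CorrelationReport:
    """Correlation screening of all 36 feature columns against yield.

    Requires at least 30 rows; zero-variance columns yield an undefined r,
    reported as missing with a warning. The report is ordered by mean |r|
    and carries the per-type optimal picks.
    """
    frame = matrix.frame
    if len(frame) < 30:
        raise InputError("correlation screening needs at least 30 rows")
    y = frame["yield"].to_numpy(float)
    r: dict[tuple[str, str], float] = {}
    for feat in FEATURES:
        for phase in PHASES:
            x = frame[column_name(feat, phase)].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero-variance column {column_name(feat, phase)}: r undefined"
                )
                r[(feat, phase)] = np.nan
                continue
            r[(feat, phase)] = float(stats.pearsonr(x, y)[0])
    mean_r = {
        feat: float(np.nanmean([r[(feat, p)] for p in PHASES])) for feat in FEATURES
    }
    report = CorrelationReport(r=r, mean_r_per_feature=mean_r)
    report.selected = select_optimal(report)
    return report


def select_optimal(report: CorrelationReport) -> dict[str, str]:
    """Per feature type, the feature with the highest mean |r| across phases.

    Ties break by the later-phase |r| (GP4 down to GP1), then lexicographic.
    """
    selected = {}
    for type_name, members in TYPE_GROUPS.items():
        def sort_key(feat: str):
            later = tuple(
                abs(report.r.get((feat, p), np.nan))
                if np.isfinite(report.r.get((feat, p), np.nan)) else -1.0
                for p in reversed(PHASES)
            )
            mean_abs = abs(report.mean_r_per_feature.get(feat, np.nan))
            mean_abs = mean_abs if np.isfinite(mean_abs) else -1.0
            return (mean_abs, later, [-ord(c) for c in feat])
        selected[type_name] = max(members, key=sort_key)
    return selected


def minmax_normalize(values: np.ndarray, lo: float | None = None,
                     hi: float | None = None) -> tuple[np.ndarray, float, float]:
    """Min-max scale to [0, 1]; degenerate columns map to 0.5.

    Returns (scaled, lo, hi) so the transform is invertible downstream.
    """
    v = np.asarray(values, float)
    lo = float(np.min(v)) if lo is None else lo
    hi = float(np.max(v)) if hi is None else hi
    if hi - lo <= 0:
        return np.full_like(v, 0.5), lo, hi
    return (v - lo) / (hi - lo), lo, hi
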