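"""Experiment design: phase combinations × feature sets × model families.

The design mirrors the forecasting study layout:

* four single growth phases (GP1..GP4), each modelled with the tree
  ensemble on all nine features of that phase, with permutation importance;
* six contiguous multi-phase combinations (GP12, GP23, GP34, GP123, GP234,
  GP1234), each crossed with four cumulative feature sets (growth state;
  + water; + temperature; + both) and two model families (tree ensemble,
  gated recurrent network) — the multi-phase sets use the per-type optimal
  features from correlation screening.

Accuracy is reported as the coefficient of determination
R² = 1 − Σ(xᵢ−yᵢ)²/Σ(xᵢ−x̄)², the root-mean-square error
RMSE = sqrt(Σ(xᵢ−yᵢ)²/n) (kg/ha) and the mean relative error
MRE = (1/n)Σ|xᵢ−yᵢ|/xᵢ × 100 (percent), with xᵢ actual and yᵢ predicted
yield. All design cells share one split and seed so model and feature
effects are not confounded with sampling; a failing cell is recorded and
the run continues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .features import (FEATURES, PHASES, TYPE_GROUPS, CorrelationReport,
                       PhaseFeatureMatrix, column_name, correlate)
from .models import (RecurrentNetConfig, SplitSpec, TreeEnsembleConfig,
                     importance, predict, split_data, train_recurrent,
                     train_tree_ensemble)

logger = logging.getLogger(__name__)

__all__ = [
    "PHASE_COMBOS",
    "MULTI_COMBOS",
    "SINGLE_COMBOS",
    "FEATURE_SETS",
    "MetricsResult",
    "ExperimentDesign",
    "EvaluationReport",
    "compute_metrics",
    "run_design",
    "render_report",
]

PHASE_COMBOS: dict[str, list[str]] = {
    "GP1": ["GP1"], "GP2": ["GP2"], "GP3": ["GP3"], "GP4": ["GP4"],
    "GP12": ["GP1", "GP2"], "GP23": ["GP2", "GP3"], "GP34": ["GP3", "GP4"],
    "GP123": ["GP1", "GP2", "GP3"], "GP234": ["GP2", "GP3", "GP4"],
    "GP1234": ["GP1", "GP2", "GP3", "GP4"],
}
SINGLE_COMBOS = ["GP1", "GP2", "GP3", "GP4"]
MULTI_COMBOS = ["GP12", "GP23", "GP34", "GP123", "GP234", "GP1234"]

#: Cumulative feature sets by type, in the order features are added.
FEATURE_SETS: dict[str, list[str]] = {
    "growth_state": ["growth_state"],
    "growth_state+water": ["growth_state", "water"],
    "growth_state+temperature": ["growth_state", "temperature"],
    "growth_state+water+temperature": ["growth_state", "water", "temperature"],
}


@dataclass(frozen=True)
class MetricsResult:
    r2: float
    rmse: float  # kg/ha
    mre: float   # percent
    n: int


def compute_metrics(actual, predicted) -> MetricsResult:
    """R², RMSE and MRE of predicted vs actual yields."""
    x = np.asarray(actual, float)
    y = np.asarray(predicted, float)
    if x.shape != y.shape or x.size == 0:
        raise InputError("actual and predicted must be equal-length and nonempty")
    if np.any(x == 0):
        raise InputError("MRE undefined: actual yield contains zero")
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if ss_tot == 0:
        raise InputError("R² undefined: zero variance in actual yields")
    ss_res = float(np.sum((x - y) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / x.size)
    mre = float(np.mean(np.abs(x - y) / x) * 100.0)
    return MetricsResult(r2=r2, rmse=rmse, mre=mre, n=int(x.size))


@dataclass
class ExperimentDesign:
    phase_combos: list[str] = field(default_factory=lambda: list(PHASE_COMBOS))
    feature_sets: list[str] = field(default_factory=lambda: list(FEATURE_SETS))
    models: list[str] = field(default_factory=lambda: ["tree_ensemble", "recurrent"])
    split: SplitSpec = field(default_factory=SplitSpec)
    tree_config: TreeEnsembleConfig = field(default_factory=TreeEnsembleConfig)
    recurrent_config: RecurrentNetConfig = field(default_factory=RecurrentNetConfig)
    #: single phases normally use the tree ensemble on all nine features only
    recurrent_singles: bool = False
    importance_repeats: int = 10

    def __post_init__(self):
        for combo in self.phase_combos:
            if combo not in PHASE_COMBOS:
                raise InputError(f"unknown phase combination '{combo}'")


@dataclass
class EvaluationReport:
    """One row per design cell plus per-cell importances."""

    rows: pd.DataFrame
    importances: dict[tuple[str, str, str], dict[str, float]]
    correlation: CorrelationReport | None = None
    selected: dict[str, str] | None = None
    failures: list[tuple[str, str, str, str]] = field(default_factory=list)


def _layout(combo: str, feature_set: str, selected: dict[str, str]):
    phases = PHASE_COMBOS[combo]
    feats = [selected[t] for t in FEATURE_SETS[feature_set]]
    return [(p, [column_name(f, p) for f in feats]) for p in phases]


def run_design(matrix: PhaseFeatureMatrix, design: ExperimentDesign,
               selected: dict[str, str] | None = None) -> EvaluationReport:
    """Train and evaluate every design cell on a shared split.

    Single-phase combos use all nine features of the phase with the tree
    ensemble; multi-phase combos use the per-type selected features under
    every feature set and both model families. Failures are isolated per
    cell. Returns the complete evaluation report.
    """
    report_corr = correlate(matrix)
    if selected is None:
        selected = report_corr.selected
    train, test = split_data(matrix, design.split)
    y_test = test["yield"].to_numpy(float)
    rows = []
    importances: dict[tuple[str, str, str], dict[str, float]] = {}
    failures = []

    def run_cell(combo, feature_set, model_kind, trainer):
        try:
            model = trainer()
            metrics = compute_metrics(y_test, predict(model, test))
            imp = importance(model, test, seed=design.split.seed,
                             n_repeats=design.importance_repeats)
            importances[(combo, feature_set, model_kind)] = imp
            rows.append({
                "phase_combo": combo, "feature_set": feature_set,
                "model": model_kind, "r2": metrics.r2, "rmse": metrics.rmse,
                "mre": metrics.mre, "n_test": metrics.n,
                "seed": design.split.seed,
            })
        except Exception as exc:  # per-cell isolation
            logger.exception("design cell (%s, %s, %s) failed",
                             combo, feature_set, model_kind)
            failures.append((combo, feature_set, model_kind, str(exc)))

    for combo in design.phase_combos:
        if combo in SINGLE_COMBOS:
            phase = combo
            cols = [column_name(f, phase) for f in FEATURES]
            run_cell(combo, "all_nine", "tree_ensemble",
                     lambda c=cols: train_tree_ensemble(train, c, design.tree_config))
            if design.recurrent_singles:
                lay = [(phase, cols)]
                run_cell(combo, "all_nine", "recurrent",
                         lambda l=lay: train_recurrent(train, l,
                                                       design.recurrent_config))
        else:
            for feature_set in design.feature_sets:
                lay = _layout(combo, feature_set, selected)
                flat = [c for _, cs in lay for c in cs]
                if "tree_ensemble" in design.models:
                    run_cell(combo, feature_set, "tree_ensemble",
                             lambda f=flat: train_tree_ensemble(
                                 train, f, design.tree_config))
                if "recurrent" in design.models:
                    run_cell(combo, feature_set, "recurrent",
                             lambda l=lay: train_recurrent(
                                 train, l, design.recurrent_config))
    frame = pd.DataFrame(
        rows, columns=["phase_combo", "feature_set", "model", "r2", "rmse",
                       "mre", "n_test", "seed"],
    )
    return EvaluationReport(rows=frame, importances=importances,
                            correlation=report_corr, selected=selected,
                            failures=failures)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

SINGLE_TABLE_COLUMNS = ["growth_phase", "r2", "rmse_kg_ha", "mre_pct"]
COMBO_TABLE_COLUMNS = [
    "phase_combo", "gru_r2", "gru_rmse_kg_ha", "gru_mre_pct",
    "rf_r2", "rf_rmse_kg_ha", "rf_mre_pct",
]


def render_report(report: EvaluationReport, outdir) -> dict[str, str]:
    """Write the report CSVs: single-phase table, best-per-combo table for
    both model families, the full cell grid, and the correlation table."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    singles = report.rows[report.rows["phase_combo"].isin(SINGLE_COMBOS)]
    singles = singles[singles["model"] == "tree_ensemble"]
    t5 = pd.DataFrame({
        "growth_phase": singles["phase_combo"],
        "r2": singles["r2"],
        "rmse_kg_ha": singles["rmse"],
        "mre_pct": singles["mre"],
    })[SINGLE_TABLE_COLUMNS]
    paths["single_phase"] = os.path.join(outdir, "single_phase_models.csv")
    t5.to_csv(paths["single_phase"], index=False)

    combo_rows = []
    for combo in MULTI_COMBOS:
        sub = report.rows[report.rows["phase_combo"] == combo]
        if sub.empty:
            continue
        row = {"phase_combo": combo}
        for model, prefix in (("recurrent", "gru"), ("tree_ensemble", "rf")):
            best = sub[sub["model"] == model].sort_values("r2", ascending=False)
            if len(best):
                row[f"{prefix}_r2"] = best.iloc[0]["r2"]
                row[f"{prefix}_rmse_kg_ha"] = best.iloc[0]["rmse"]
                row[f"{prefix}_mre_pct"] = best.iloc[0]["mre"]
            else:
                row[f"{prefix}_r2"] = np.nan
                row[f"{prefix}_rmse_kg_ha"] = np.nan
                row[f"{prefix}_mre_pct"] = np.nan
        combo_rows.append(row)
    t6 = pd.DataFrame(combo_rows, columns=COMBO_TABLE_COLUMNS)
    paths["combo_best"] = os.path.join(outdir, "combo_best_models.csv")
    t6.to_csv(paths["combo_best"], index=False)

    paths["all_cells"] = os.path.join(outdir, "design_cells.csv")
    report.rows.to_csv(paths["all_cells"], index=False)

    if report.correlation is not None:
        paths["correlation"] = os.path.join(outdir, "feature_correlations.csv")
        report.correlation.as_frame().to_csv(paths["correlation"],
                                             index_label="feature")
    return paths
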