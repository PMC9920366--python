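# maizephase

Phase-wise yield forecasting for summer maize: a reduced process-based
growth simulator drives a large synthetic scenario ensemble, thermal-time
staging splits each season into four growth phases, and per-phase yield
factors feed two regressors — a random forest and a gated recurrent unit
(GRU) network — to quantify how much of the final yield is predictable at
each point of the season.

## Who this is for

Agro-meteorologists and crop-modelling practitioners who want a
self-contained, fully seeded testbed for the question *"how early in the
season can grain yield be predicted, and from which variables?"* — without
needing a station archive or a full WOFOST installation. All inputs are
generated synthetically (calibrated to a warm-temperate monsoon climate,
annual mean temperature 11–14 °C, annual precipitation 550–950 mm); real
station data can be substituted through the daily weather CSV interface.

## The method

1. **Scenario ensemble.** A reduced WOFOST-style daily simulator (thermal
   development, Beer's-law light interception, radiation-use-efficiency
   growth, DVS-indexed partitioning, thermal-age leaf senescence, one-layer
   soil water bucket, potential vs water-limited modes) is run over a
   Cartesian grid of pseudo-varieties (TSUM1 ∈ [800, 1000], TSUM2 ∈
   [750, 950] °C·d, SLATB1 ∈ [0.0026, 0.0035] ha/kg), three loam soils,
   three sowing dates, two water modes and 21 synthetic weather years —
   ~10,000 scenarios at desk scale. Each trace records daily DVS, LAI, TRA,
   SM and organ biomass; yield is storage-organ biomass at maturity.
2. **Thermal-time staging.** Daily effective temperature
   Te = clamp(T − T_base, 0, T_max − T_base) with T_base = 8 °C,
   T_max = 29 °C is accumulated from a calendar-day phenology (emergence
   late June → jointing mid-July → flowering early August → milk maturity
   late August → maturity mid-September); multi-year means give cumulative-Te
   thresholds that segment every trace into four growth phases GP1..GP4.
3. **Per-phase yield factors.** Nine features per phase (LAI mean/sum/max/
   rate; TRA, SM, precipitation sums; mean and maximum temperature sums);
   Pearson screening selects the best feature per type — on the default
   ensemble: LAI-sum, TRA-sum, Tmax-sum.
4. **Forecasting experiment.** Single phases (random forest, all nine
   features) and six contiguous multi-phase combinations (GP12 … GP1234,
   four cumulative feature sets, both model families, shared 9:1 split) are
   evaluated with R² = 1 − Σ(xᵢ−yᵢ)²/Σ(xᵢ−x̄)², RMSE = √(Σ(xᵢ−yᵢ)²/n) and
   MRE = (1/n)Σ|xᵢ−yᵢ|/xᵢ·100. The GRU (implemented in NumPy: update/reset
   gates, BPTT, Adam, dropout, early stopping) consumes one timestep per
   growth phase.

## Worked example

```python
from maizephase import (ClimateProfile, GridSpec, generate_weather,
                        calibrate_thresholds, build_scenario_grid,
                        run_ensemble, segment_trace, validate_stage_dvs)

weather = generate_weather(ClimateProfile(), n_years=21, seed=7)
thresholds = calibrate_thresholds([weather])
print({k: round(v) for k, v in thresholds.te_at_stage.items()})
# {'emergence': 0, 'jointing': 370, 'flowering': 747, 'milk_maturity': 1093,
#  'maturity': 1394}

grid = GridSpec(site_years=[(weather, y) for y in weather.years])
scenarios = build_scenario_grid(grid)         # 10,206 scenarios
traces = run_ensemble(scenarios)
bounds = [segment_trace(t, thresholds) for t in traces]
report = validate_stage_dvs(traces, bounds)
print(round(report["flowering_rel_error_pct"], 1))   # 15.3
print(round(report["maturity_rel_error_pct"], 1))    # 20.3
```

The thresholds are the mean growing-degree-day totals between the calendar
stages; the two percentages are the mean deviation of the simulated
development stage from its true value (1 at flowering, 2 at maturity) on
the day each threshold is crossed. On purely synthetic weather the two
clocks share one thermal scale, so these errors reflect the gap between the
verbal stage calendar and the varieties' thermal requirements (see
`docs/methods.md` for why this gap is structural).

A full run — simulation through the 52-cell forecasting experiment — is one
command:

```bash
maizephase run-all --out runs/demo --seed 1
```

which writes the weather files, the daily trace table, thermal thresholds,
phase bounds, the 36-column feature matrix, and the report tables
(`single_phase_models.csv`, `combo_best_models.csv`,
`feature_correlations.csv`, `design_cells.csv`). The staged subcommands
`simulate`, `phase`, `featurize`, `train` and `evaluate` run the same
pipeline incrementally over those CSV artifacts.

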