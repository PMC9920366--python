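# Methods

This note documents the models inside `maizephase`, the choices that were
genuinely open, and what the synthetic testbed can and cannot show about
real field data.

## Synthetic weather

The generator emulates the warm-temperate continental monsoon climate of a
summer-maize region (annual mean temperature 11–14 °C, annual precipitation
550–950 mm, July mean near 27 °C):

* **Temperature** — an annual sinusoid (default mean 12.5 °C, amplitude
  14.5 °C, maximum on 20 July) plus an AR(1) anomaly (coefficient 0.70,
  innovation SD 2.0 °C). Daily minimum/maximum are the mean ± half a
  stochastic diurnal range (mean 9 °C, narrower on wet days).
* **Precipitation** — a two-state Markov occurrence chain whose transition
  probabilities are modulated seasonally (relative amplitude 0.85, peak in
  mid-July) around annual-mean values P(wet|wet) = 0.45, P(wet|dry) = 0.22,
  with gamma wet-day amounts (shape 1.0, scale 5.9 mm). The seasonal
  modulation matters: roughly two thirds of annual rain falls June–September,
  which simultaneously supplies the rainfed crop and — through the
  rain–sunshine coupling — produces realistic cloudy-summer radiation
  (July global radiation ≈ 17 MJ m⁻² day⁻¹). Defaults were calibrated once
  so that 50-year runs put ≥ 95 % of years inside the stated climate bands.
* **Radiation** — sunshine fraction drawn per day (dry days 0.45–0.90 of
  astronomical day length, wet days 0.05–0.40), converted with the Angstrom
  equation Rs = Ra(a + b·n/N), a = 0.25, b = 0.50 (standard values; the
  station coefficients are not published for the region), with Ra and N from
  FAO-56 solar geometry.
* **Humidity and wind** — vapour pressure = Tetens saturation pressure at
  the daily mean times a relative-humidity draw (higher on wet days); wind
  lognormal (median ≈ 2 m/s).

What the generator does **not** emulate: spatial station-to-station
gradients, multi-day synoptic rain systems, heat waves with correlated
drought, and inter-annual (ENSO-like) persistence. Consequences for the
study are discussed under *Limitations*.

## Reduced crop model

A daily-step, single-layer reduced re-implementation of the WOFOST
structure; state variables are DVS, LAI, per-organ dry biomass (leaf, stem,
storage, root), root-zone soil moisture, and the transpiration-reduction
factor. Ordering per day: thermal time → development; Priestley–Taylor
reference ET → potential transpiration; moisture stress → actual TRA; light
interception; growth; partitioning; leaf senescence; water-bucket update.

Key equations and defaults (units in parentheses):

| Component | Form | Default |
|---|---|---|
| Development | dDVS = Te/TSUM1 (DVS<1), Te/TSUM2 (1≤DVS<2), cap 2 | TSUM central 900/850 °C·d |
| Effective temperature | clamp(T−8, 0, 21) (°C·d) | T_base 8 °C, cap 29 °C |
| Emergence | cumulative post-sowing Te ≥ 70 °C·d | |
| Interception | f = 1 − exp(−k·LAI) | k = 0.6 |
| Growth | RUE · f · 0.5·Rs · stress (kg ha⁻¹ d⁻¹ after unit conversion) | RUE = 2.5 g/MJ |
| Reference ET | Priestley–Taylor α=1.26 on Rn = 0.75·Rs − 1.0 MJ | |
| Crop transpiration | f · kc(DVS) · ET0, kc 0.5→1.2→0.6 at DVS 0/1/2 | |
| Stress | clamp((SM−SMW)/(SM_crit−SMW), 0, 1), SM_crit = SMW+0.55(SMFCF−SMW) | |
| Senescence | cohorts age by (T−T_base,leaf)/(35−T_base,leaf) per day, die past SPAN | SPAN 40 d |

Design choices that were genuinely open:

* **Radiation-use efficiency 2.5 g/MJ.** The model books growth as *net*
  total dry matter per MJ of intercepted PAR, with no separate maintenance
  respiration or organ-conversion losses. The gross above-ground literature
  value (~3.3, often rounded to 3.0) applied in this net role produced
  ~25 t/ha season biomass and 13–14 t/ha potential grain yield —
  agronomically implausible. The seasonal net value for maize (≈ 2.4–2.7
  g/MJ) was adopted; the default desk ensemble then averages ≈ 8.5 t/ha
  (potential ≈ 11, water-limited ≈ 7.5–8), in line with regional simulated
  yields.
* **Specific leaf area declines with development.** The published crop
  parameter is SLA at DVS = 0 (0.0026–0.0035 ha/kg); leaves formed later are
  thicker. SLA follows the standard maize shape (linear halving by DVS 0.8).
  A constant SLA gives LAI maxima above 10, which no maize canopy reaches.
* **Partitioning table** (DVS → leaf/stem/storage/root): 0 → .55/.25/0/.20;
  0.9 → .25/.55/0/.20; 1.0 → .05/.25/.65/.05; 1.3 → 0/.05/.95/0; ≥1.5 →
  0/0/1/0, linearly interpolated, storage onset forced at DVS 0.95 (the
  pre-onset storage share goes to stem). Shaped on published maize tables;
  all constants are exposed in configuration.
* **Fixed-depth water bucket.** The root-zone store uses the full profile
  depth (default 100 cm) from emergence. A growing root zone would move
  water across the accounting boundary without a physical flux, breaking
  exact closure of ΔW = rain + irrigation − TRA − soil evaporation −
  drainage, which the implementation maintains to < 10⁻⁶ mm/day; with a
  uniform-moisture bucket the depth has no other effect on the model.
  Potential mode pins SM at field capacity — the irrigation flux is whatever
  closes the balance.
* **Season cutoff 130 days after sowing.** Slow (high-TSUM) varieties sown
  late may not reach DVS 2; their traces end at the cutoff with the
  accumulated storage biomass as yield (a realistic harvest-date truncation).
  Traces still below DVS 1 at cutoff are flagged immature and excluded from
  ensembles; with the default climate none occur.
* **Initial state.** 50 kg/ha total dry weight at emergence, split by the
  DVS-0 partition fractions; initial soil moisture at field capacity.

## Thermal-time staging and its structural error

Stage thresholds are the multi-year mean cumulative Te from the calendar
emergence date to each stage date (half-open intervals); segmentation finds
the first day each trace's own cumulative Te (from simulated emergence)
reaches a threshold. Estimated DVS values are thresholds mapped through the
central thermal clock (900/850 °C·d).

Because the crop's development and the staging thresholds share one thermal
scale, the simulated DVS at a threshold crossing is algebraically
threshold/TSUM1 (or 1 + (threshold − TSUM1)/TSUM2) — the weather cancels.
The verbal calendar allows ~41 days from emergence to flowering and ~82 to
maturity; at a capped 21 °C·d/day this bounds the flowering threshold below
~860 °C·d and the maturity threshold below ~1720 °C·d, while the variety
grid demands ≈ 900 and ≈ 1750 for zero error. Under the default climate the
thresholds come out ≈ 750 and ≈ 1390, so the mean DVS deviations at
flowering and maturity are ≈ 15 % and ≈ 20 % — a structural property of
staging a short verbal calendar with a single capped thermal scale, not a
tuning artifact. Reference systems that report near-zero errors use a
separate (lower-base, uncapped) internal development scale, which this
package deliberately does not introduce: one thermal scale is used
throughout, as the staging method itself prescribes.

## Features, screening and models

The nine per-phase factors and Pearson screening follow the experiment
design; `lai_rate` is defined here as net LAI change divided by phase length
(no standard definition exists); SM-sum keeps its odd cm³/cm³·d unit;
temperature sums use
raw (uncapped) daily means/maxima. On the default ensemble the per-type
picks are LAI-sum, TRA-sum and Tmax-sum.

The tree ensemble is scikit-learn's RandomForestRegressor under a
cross-validated grid search (n_estimators {100, 300}; max_depth {8, 16,
none}; max_features {√p, p/3, p}). The gated recurrent network is a NumPy
implementation (no deep-learning framework is required): stacked GRU cells
in the standard update/reset formulation, a 32-unit ReLU dense head, MSE
loss, Adam (lr 2.5·10⁻³, batch 128, up to 500 epochs), inverted dropout 0.1
between layers, early stopping on a 10 % validation slice (patience 60)
with learning-rate halving on 15-epoch plateaus, float32 arithmetic.
Backpropagation through time is verified against central finite differences
in the test suite. Min-max normalization is applied to inputs (both
families) and to the target (recurrent only, inverted at prediction).
Importance is model-agnostic permutation importance on held-out data
(10 permutations, R² drop, floored at zero, normalized to sum 1).

## What the synthetic testbed shows — and what it cannot

The ensemble is **deterministic given its factor levels** (variety, soil,
sowing, water mode, weather year): there is no measurement noise, no
within-field heterogeneity, and only 21 weather realizations. Early-season
features therefore identify soil, variety (through early LAI) and weather
year far more sharply than real data would, and a lookup-style learner can
exploit that. Two consequences observed on the default ensemble:

* single-phase predictability starts high (GP1 R² ≈ 0.8 instead of the
  near-zero value real multi-station data produce) although the *ordering*
  GP1 ≤ GP2 ≤ GP3 ≤ GP4 is preserved;
* the random forest matches or exceeds the recurrent network on phase
  combinations whose information is dominated by that discrete lookup
  (GP23, GP123), while the two families are equivalent where the signal is
  smoother (GP12, GP34, GP1234).

Passing model-pattern tests here therefore demonstrates internal
consistency of the pipeline, not transferability to field data; conversely,
the deviations just listed are properties of a deterministic reduced
simulator, not implementation defects.

## Problem sizes

Unit tests run on a 216-scenario, 2-year ensemble and a 32-scenario
fixture; the acceptance suite and `scripts/acceptance.py` use the default
desk-scale study (1 site × 21 years × 27 pseudo-varieties × 3 soils × 3
sowing dates × 2 water modes = 10,206 scenarios), the scale at which the
whole-season GRU model is evaluated.
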