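"""Reduced WOFOST-style daily summer-maize growth simulator.

The simulator reproduces the structure of a process-based crop model —
thermal-time development, light interception, radiation-use-efficiency
growth, DVS-driven assimilate partitioning, thermal-age leaf senescence and
a single-layer soil water bucket — with the same state variables a full
model exposes (DVS, LAI, TRA, SM, per-organ biomass) and the same two
production modes (potential: implicit unlimited irrigation; water-limited:
rainfed with transpiration stress). The fidelity target is structural
(variable set, orderings, dominance of potential over water-limited yield),
not numerical agreement with any particular full model.

Daily order of operations: thermal time → development stage; reference
evapotranspiration (Priestley–Taylor) → potential transpiration; soil
moisture → stress factor → actual transpiration; light interception
fint = 1 − exp(−k·LAI); gross growth = RUE · fint · PAR · stress;
partitioning by DVS; leaf area growth and senescence; soil-water bucket
update. The water balance closes exactly:
ΔW = rain + irrigation − transpiration − soil evaporation − drainage.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError, SequencingError
from .phasing import ThermalConfig, effective_daily_te
from .weather import WeatherRecord, WeatherSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CropParameters",
    "SoilParameters",
    "ManagementConfig",
    "PhotoperiodConfig",
    "Scenario",
    "DailyState",
    "SimulationTrace",
    "GridSpec",
    "advance_dvs",
    "daily_step",
    "run_simulation",
    "build_scenario_grid",
    "run_ensemble",
    "SOIL_PRESETS",
]

#: Default DVS-indexed assimilate partitioning (leaf, stem, storage, root),
#: linearly interpolated; shaped on published maize tables. Storage
#: allocation is forced to zero below the onset node.
DEFAULT_PARTITION_TABLE = (
    (0.0, 0.55, 0.25, 0.00, 0.20),
    (0.9, 0.25, 0.55, 0.00, 0.20),
    (1.0, 0.05, 0.25, 0.65, 0.05),
    (1.3, 0.00, 0.05, 0.95, 0.00),
    (1.5, 0.00, 0.00, 1.00, 0.00),
    (2.0, 0.00, 0.00, 1.00, 0.00),
)
STORAGE_ONSET_DVS = 0.95

#: Specific leaf area declines with development (leaves thicken); the crop
#: parameter fixes the DVS=0 value, this table the relative shape, following
#: published maize tables where SLA roughly halves by anthesis.
SLA_SHAPE_TABLE = ((0.0, 1.0), (0.8, 0.5), (2.0, 0.5))

#: Crop coefficient nodes (DVS, kc) for potential transpiration.
KC_TABLE = ((0.0, 0.5), (1.0, 1.2), (2.0, 0.6))

SEASON_CUTOFF_DAYS = 130  # days after sowing
INITIAL_TOTAL_DW = 50.0  # kg/ha dry weight at emergence
PRIESTLEY_TAYLOR_ALPHA = 1.26
PSYCHROMETRIC_GAMMA = 0.066  # kPa/°C
LATENT_HEAT = 2.45  # MJ/kg
NET_RADIATION_FRACTION = 0.75  # shortwave-to-net conversion
NET_LONGWAVE_LOSS = 1.0  # MJ/m2/day flat longwave loss
LEAF_AGING_REF_TEMP = 35.0  # °C reference for SPAN


@dataclass(frozen=True)
class CropParameters:
    """Pseudo-variety parameters; thermal and leaf parameters are bounded
    to the calibration ranges of the regional summer-maize ensemble."""

    tsum1: float = 900.0          # °C·d emergence -> anthesis
    tsum2: float = 850.0          # °C·d anthesis -> maturity
    slatb1: float = 0.003         # ha leaf per kg at DVS=0
    span: float = 40.0            # leaf life span at 35 °C, days
    tbase_leafage: float = 9.0    # °C lower threshold for leaf aging
    tsum_emergence: float = 70.0  # °C·d sowing -> emergence
    rue: float = 2.5              # g dry matter per MJ intercepted PAR (net seasonal)
    k_ext: float = 0.6            # canopy light extinction coefficient
    partition_table: tuple = DEFAULT_PARTITION_TABLE

    def __post_init__(self):
        bounds = {
            "tsum1": (800.0, 1000.0),
            "tsum2": (750.0, 950.0),
            "slatb1": (0.0026, 0.0035),
            "span": (35.0, 45.0),
            "tbase_leafage": (8.0, 10.0),
        }
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name}={v} outside calibration range [{lo}, {hi}]")
        if self.tsum_emergence <= 0 or self.rue <= 0 or self.k_ext <= 0:
            raise ConfigurationError("tsum_emergence, rue and k_ext must be positive")
        for node in self.partition_table:
            dvs, *fracs = node
            if any(f < 0 or f > 1 for f in fracs):
                raise ConfigurationError(f"partition fractions at DVS={dvs} outside [0,1]")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ConfigurationError(f"partition fractions at DVS={dvs} do not sum to 1")


@dataclass(frozen=True)
class SoilParameters:
    """Volumetric moisture constants of a single-layer soil."""

    smw: float    # wilting point, cm3/cm3
    sm0: float    # saturation, cm3/cm3
    smfcf: float  # field capacity, cm3/cm3
    loam_type: str = "loam"
    rooting_depth_max: float = 100.0  # cm

    def __post_init__(self):
        if not 0.0 < self.smw < self.smfcf < self.sm0 < 1.0:
            raise ConfigurationError(
                f"soil '{self.loam_type}': need 0 < smw < smfcf < sm0 < 1 "
                f"(got smw={self.smw}, smfcf={self.smfcf}, sm0={self.sm0})"
            )
        if self.rooting_depth_max <= 0:
            raise ConfigurationError("rooting_depth_max must be positive")


SOIL_PRESETS = {
    "sandy_loam": SoilParameters(smw=0.06, sm0=0.35, smfcf=0.28, loam_type="sandy_loam"),
    "light_loam": SoilParameters(smw=0.09, sm0=0.34, smfcf=0.28, loam_type="light_loam"),
    "medium_loam": SoilParameters(smw=0.11, sm0=0.34, smfcf=0.28, loam_type="medium_loam"),
}

DEFAULT_SOWING_DATES = ("06-01", "06-10", "06-19")
WATER_MODES = ("potential", "water_limited")


@dataclass(frozen=True)
class ManagementConfig:
    sowing_date: str = "06-01"  # month-day
    water_mode: str = "potential"

    def __post_init__(self):
        try:
            month, day = (int(p) for p in self.sowing_date.split("-"))
            dt.date(2001, month, day)
        except Exception:
            raise ConfigurationError(f"sowing_date '{self.sowing_date}' is not a month-day")
        if self.water_mode not in WATER_MODES:
            raise ConfigurationError(f"water_mode must be one of {WATER_MODES}")

    def sowing_in_year(self, year: int) -> dt.date:
        month, day = (int(p) for p in self.sowing_date.split("-"))
        return dt.date(year, month, day)


@dataclass(frozen=True)
class PhotoperiodConfig:
    """Day-length reduction of the development rate; disabled by default, as
    photoperiod response is usually neglected for modern summer maize."""

    enabled: bool = False
    p_actual: float = 14.0
    p_critical: float = 12.0
    p_optimal: float = 16.0

    def __post_init__(self):
        if self.enabled and not self.p_critical < self.p_optimal:
            raise ConfigurationError("p_critical must be below p_optimal when enabled")

    def factor(self) -> float:
        if not self.enabled:
            return 1.0
        f = (self.p_actual - self.p_critical) / (self.p_optimal - self.p_critical)
        return float(min(1.0, max(0.0, f)))


@dataclass(frozen=True)
class Scenario:
    crop: CropParameters
    soil: SoilParameters
    management: ManagementConfig
    weather: WeatherSeries
    year: int
    scenario_id: str

    @property
    def levels(self) -> dict:
        """Factor levels of this scenario (provenance for the feature matrix)."""
        return {
            "site": self.weather.site_id,
            "year": self.year,
            "tsum1": self.crop.tsum1,
            "tsum2": self.crop.tsum2,
            "slatb1": self.crop.slatb1,
            "span": self.crop.span,
            "tbase_leafage": self.crop.tbase_leafage,
            "soil": self.soil.loam_type,
            "sowing_date": self.management.sowing_date,
            "water_mode": self.management.water_mode,
        }


@dataclass
class DailyState:
    date: dt.date
    dvs: float
    lai: float
    tra: float
    sm: float
    w_leaf: float
    w_stem: float
    w_storage: float
    w_root: float
    stress: float
    # internal senescence bookkeeping (not part of the observable state)
    leaf_age_odometer: float = 0.0
    cohorts: tuple = ()  # ((birth_odometer, lai, mass), ...)


@dataclass
class SimulationTrace:
    """Daily state arrays from emergence to maturity (or the season cutoff)."""

    scenario_id: str
    dates: np.ndarray  # dt.date objects
    dvs: np.ndarray
    lai: np.ndarray
    tra: np.ndarray
    sm: np.ndarray
    w_leaf: np.ndarray
    w_stem: np.ndarray
    w_storage: np.ndarray
    w_root: np.ndarray
    stress: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    # water-balance ledger, mm/day
    irrigation: np.ndarray
    soil_evap: np.ndarray
    drainage: np.ndarray
    storage_mm: np.ndarray  # root-zone water at end of day
    yield_final: float = 0.0
    maturity_date: dt.date | None = None
    mature: bool = False
    immature: bool = False  # DVS < 1 at season cutoff: excluded from ensembles
    emergence_date: dt.date | None = None

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def states(self) -> list[DailyState]:
        return [
            DailyState(
                date=self.dates[i], dvs=float(self.dvs[i]), lai=float(self.lai[i]),
                tra=float(self.tra[i]), sm=float(self.sm[i]),
                w_leaf=float(self.w_leaf[i]), w_stem=float(self.w_stem[i]),
                w_storage=float(self.w_storage[i]), w_root=float(self.w_root[i]),
                stress=float(self.stress[i]),
            )
            for i in range(len(self.dates))
        ]


# ---------------------------------------------------------------------------
# Development
# ---------------------------------------------------------------------------

def advance_dvs(state: DailyState, te_day: float, crop: CropParameters,
                photoperiod: PhotoperiodConfig = PhotoperiodConfig()) -> float:
    """Next-day development stage under the two-segment thermal clock.

    DVS advances by Fpr·Te/TSUM1 before anthesis (DVS < 1) and by
    Fpr·Te/TSUM2 afterwards, capped at 2; Fpr = 1 with photoperiod disabled.
    """
    if te_day < 0:
        raise InputError("te_day must be nonnegative")
    fpr = photoperiod.factor()
    dvs = state.dvs
    inc = fpr * te_day / (crop.tsum1 if dvs < 1.0 else crop.tsum2)
    return min(2.0, dvs + inc)


def _interp_nodes(x: float, nodes, values) -> float:
    """Piecewise-linear interpolation over a short sorted node table."""
    if x <= nodes[0]:
        return values[0]
    for i in range(1, len(nodes)):
        if x <= nodes[i]:
            w = (x - nodes[i - 1]) / (nodes[i] - nodes[i - 1])
            return values[i - 1] + w * (values[i] - values[i - 1])
    return values[-1]


def _partition(crop: CropParameters, dvs: float) -> tuple[float, float, float, float]:
    table = crop.partition_table
    nodes = [row[0] for row in table]
    fl = _interp_nodes(dvs, nodes, [r[1] for r in table])
    fs = _interp_nodes(dvs, nodes, [r[2] for r in table])
    fo = _interp_nodes(dvs, nodes, [r[3] for r in table])
    fr = _interp_nodes(dvs, nodes, [r[4] for r in table])
    if dvs < STORAGE_ONSET_DVS:  # storage onset: reallocate to stem
        fs += fo
        fo = 0.0
    return fl, fs, fo, fr


_KC_NODES = [n for n, _ in KC_TABLE]
_KC_VALUES = [v for _, v in KC_TABLE]
_SLA_NODES = [n for n, _ in SLA_SHAPE_TABLE]
_SLA_VALUES = [v for _, v in SLA_SHAPE_TABLE]


def _kc(dvs: float) -> float:
    return _interp_nodes(dvs, _KC_NODES, _KC_VALUES)


def _sla(crop: CropParameters, dvs: float) -> float:
    """Specific leaf area (ha/kg) at a development stage."""
    return crop.slatb1 * _interp_nodes(dvs, _SLA_NODES, _SLA_VALUES)


def _reference_et(irrad_kj: float, tmean: float) -> float:
    """Priestley–Taylor reference evapotranspiration, mm/day."""
    rs_mj = irrad_kj / 1000.0
    rn = NET_RADIATION_FRACTION * rs_mj - NET_LONGWAVE_LOSS
    if rn <= 0.0:
        return 0.0
    es = 0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))
    delta = 4098.0 * es / (tmean + 237.3) ** 2
    et0 = PRIESTLEY_TAYLOR_ALPHA * (delta / (delta + PSYCHROMETRIC_GAMMA)) * rn / LATENT_HEAT
    return max(0.0, et0)


# ---------------------------------------------------------------------------
# Daily step
# ---------------------------------------------------------------------------

def daily_step(state: DailyState, weather: WeatherRecord, scenario: Scenario,
               thermal: ThermalConfig = ThermalConfig(),
               photoperiod: PhotoperiodConfig = PhotoperiodConfig()) -> DailyState:
    """Advance one day. ``weather`` must be dated state.date + 1 day."""
    if (weather.day - state.date).days != 1:
        raise SequencingError(
            f"weather record {weather.day} does not follow state date {state.date}"
        )
    crop, soil = scenario.crop, scenario.soil
    water_limited = scenario.management.water_mode == "water_limited"
    cohorts = [list(c) for c in state.cohorts] or [[0.0, state.lai, state.w_leaf]]
    out = _step(
        dvs=state.dvs, lai=state.lai, sm=state.sm,
        w_leaf=state.w_leaf, w_stem=state.w_stem,
        w_storage=state.w_storage, w_root=state.w_root,
        odometer=state.leaf_age_odometer, cohorts=cohorts,
        tmean=weather.tmean, irrad=weather.irrad, rain=weather.rain,
        crop=crop, soil=soil, water_limited=water_limited,
        thermal=thermal, fpr=photoperiod.factor(),
    )
    return DailyState(
        date=weather.day, dvs=out["dvs"], lai=out["lai"], tra=out["tra"],
        sm=out["sm"], w_leaf=out["w_leaf"], w_stem=out["w_stem"],
        w_storage=out["w_storage"], w_root=out["w_root"], stress=out["stress"],
        leaf_age_odometer=out["odometer"],
        cohorts=tuple(tuple(c) for c in out["cohorts"]),
    )


def _step(*, dvs, lai, sm, w_leaf, w_stem, w_storage, w_root, odometer, cohorts,
          tmean, irrad, rain, crop, soil, water_limited, thermal, fpr):
    """One day of the reduced model; shared by daily_step and run_simulation."""
    # 1. thermal time -> development
    te = min(max(tmean - thermal.tbase, 0.0), thermal.tmax_cap - thermal.tbase)
    dvs = min(2.0, dvs + fpr * te / (crop.tsum1 if dvs < 1.0 else crop.tsum2))

    # 2. reference ET -> potential transpiration and soil evaporation
    et0 = _reference_et(irrad, tmean)
    fint = 1.0 - math.exp(-crop.k_ext * lai)
    t_pot = fint * _kc(dvs) * et0
    e_pot = (1.0 - fint) * et0

    # 3. soil-moisture stress -> actual fluxes
    depth_mm = soil.rooting_depth_max * 10.0
    sm_crit = soil.smw + 0.55 * (soil.smfcf - soil.smw)
    if water_limited:
        stress = min(1.0, max(0.0, (sm - soil.smw) / (sm_crit - soil.smw)))
        e_red = min(1.0, max(0.0, (sm - soil.smw) / (soil.smfcf - soil.smw)))
    else:
        stress = 1.0
        e_red = 1.0
    tra = stress * t_pot
    evap = e_red * e_pot
    if water_limited:
        available = max(0.0, (sm - soil.smw) * depth_mm)
        demand = tra + evap
        if demand > available and demand > 0:
            scale = available / demand
            tra *= scale
            evap *= scale

    # 4. growth and partitioning
    par = 0.5 * irrad / 1000.0  # MJ PAR per m2
    growth = crop.rue * fint * par * stress * 10.0  # kg dry matter / ha / day
    fl, fs, fo, fr = _partition(crop, dvs)
    leaf_inc = fl * growth
    sla = _sla(crop, dvs)
    w_leaf += leaf_inc
    w_stem += fs * growth
    w_storage += fo * growth
    w_root += fr * growth
    lai += leaf_inc * sla

    # 5. leaf senescence by thermal age (SPAN days at the 35 °C reference)
    if leaf_inc > 0:
        cohorts.append([odometer, leaf_inc * sla, leaf_inc])
    aging = max(0.0, tmean - crop.tbase_leafage) / (LEAF_AGING_REF_TEMP - crop.tbase_leafage)
    odometer += aging
    while cohorts and odometer - cohorts[0][0] > crop.span:
        _, dead_lai, dead_mass = cohorts.pop(0)
        lai = max(0.0, lai - dead_lai)
        w_leaf = max(0.0, w_leaf - dead_mass)

    # 6. soil-water bucket update (exact closure)
    w_before = sm * depth_mm
    if water_limited:
        w_after = w_before + rain - tra - evap
        drainage = max(0.0, w_after - soil.smfcf * depth_mm)
        w_after -= drainage
        irrigation = 0.0
        sm = w_after / depth_mm
    else:
        # potential mode: moisture pinned at field capacity by implicit irrigation
        irrigation = max(0.0, tra + evap - rain)
        drainage = max(0.0, rain - tra - evap)
        sm = soil.smfcf
        w_after = w_before  # unchanged by construction
    return {
        "dvs": dvs, "lai": lai, "sm": sm, "w_leaf": w_leaf, "w_stem": w_stem,
        "w_storage": w_storage, "w_root": w_root, "stress": stress, "tra": tra,
        "odometer": odometer, "cohorts": cohorts, "irrigation": irrigation,
        "soil_evap": evap, "drainage": drainage, "rain": rain,
        "storage_mm": w_after,
    }


# ---------------------------------------------------------------------------
# Season loop
# ---------------------------------------------------------------------------

def run_simulation(scenario: Scenario, thermal: ThermalConfig = ThermalConfig(),
                   photoperiod: PhotoperiodConfig = PhotoperiodConfig(),
                   season_cutoff_days: int = SEASON_CUTOFF_DAYS) -> SimulationTrace:
    """Simulate one scenario from emergence to maturity or the season cutoff.

    Emergence falls on the first day after sowing whose cumulative effective
    temperature reaches the sowing→emergence requirement. The trace ends when
    DVS reaches 2 or ``season_cutoff_days`` after sowing; a trace still below
    DVS 1 at the cutoff is flagged immature.
    """
    crop, soil = scenario.crop, scenario.soil
    sowing = scenario.management.sowing_in_year(scenario.year)
    horizon = season_cutoff_days + 1
    try:
        w = scenario.weather.arrays(sowing, horizon)
    except InputError as exc:
        raise InputError(
            f"scenario {scenario.scenario_id}: weather must cover sowing through "
            f"{season_cutoff_days} days after ({exc})"
        ) from exc
    tmean_all = w["TMEAN"]
    te_all = effective_daily_te(tmean_all, thermal)

    # emergence: first day index d >= 1 with sum(te[1..d]) >= tsum_emergence
    cum = np.cumsum(te_all[1:])
    hits = np.nonzero(cum >= crop.tsum_emergence)[0]
    if len(hits) == 0:
        return _empty_trace(scenario, immature=True)
    em = int(hits[0]) + 1  # day index relative to sowing

    water_limited = scenario.management.water_mode == "water_limited"
    fpr = photoperiod.factor()
    fl0, fs0, _, fr0 = _partition(crop, 0.0)
    w_leaf = INITIAL_TOTAL_DW * fl0
    w_stem = INITIAL_TOTAL_DW * fs0
    w_root = INITIAL_TOTAL_DW * fr0
    w_storage = 0.0
    lai = w_leaf * crop.slatb1
    sm = soil.smfcf
    dvs = 0.0
    odometer = 0.0
    cohorts: list[list[float]] = [[0.0, lai, w_leaf]]

    n_max = horizon - em
    cols = ("dvs", "lai", "tra", "sm", "w_leaf", "w_stem", "w_storage", "w_root",
            "stress", "irrigation", "soil_evap", "drainage", "storage_mm")
    rec = {c: np.empty(n_max) for c in cols}
    n = 0
    for d in range(em, horizon):
        out = _step(
            dvs=dvs, lai=lai, sm=sm, w_leaf=w_leaf, w_stem=w_stem,
            w_storage=w_storage, w_root=w_root, odometer=odometer,
            cohorts=cohorts, tmean=tmean_all[d], irrad=w["IRRAD"][d],
            rain=w["RAIN"][d], crop=crop, soil=soil,
            water_limited=water_limited, thermal=thermal, fpr=fpr,
        )
        dvs, lai, sm = out["dvs"], out["lai"], out["sm"]
        w_leaf, w_stem = out["w_leaf"], out["w_stem"]
        w_storage, w_root = out["w_storage"], out["w_root"]
        odometer, cohorts = out["odometer"], out["cohorts"]
        for c in cols:
            rec[c][n] = out[c]
        n += 1
        if dvs >= 2.0:
            break

    sl = slice(0, n)
    dates = w["DAY"][em:em + n]
    mature = dvs >= 2.0
    trace = SimulationTrace(
        scenario_id=scenario.scenario_id,
        dates=dates,
        tmean=tmean_all[em:em + n],
        tmax=w["TMAX"][em:em + n],
        rain=w["RAIN"][em:em + n],
        yield_final=float(rec["w_storage"][n - 1]) if n else 0.0,
        maturity_date=dates[-1] if (mature and n) else None,
        mature=mature,
        immature=dvs < 1.0,
        emergence_date=w["DAY"][em],
        **{c: rec[c][sl].copy() for c in cols if c != "rain"},
    )
    if trace.immature:
        logger.info("scenario %s immature at season cutoff (DVS=%.2f)",
                    scenario.scenario_id, dvs)
    return trace


def _empty_trace(scenario: Scenario, immature: bool) -> SimulationTrace:
    z = np.empty(0)
    return SimulationTrace(
        scenario_id=scenario.scenario_id, dates=np.empty(0, dtype=object),
        dvs=z, lai=z, tra=z, sm=z, w_leaf=z, w_stem=z, w_storage=z, w_root=z,
        stress=z, tmean=z, tmax=z, rain=z, irrigation=z, soil_evap=z,
        drainage=z, storage_mm=z, yield_final=0.0, maturity_date=None,
        mature=False, immature=immature,
    )


# ---------------------------------------------------------------------------
# Scenario grids and ensembles
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Cartesian scenario grid: pseudo-varieties × soils × sowings × modes ×
    weather site-years."""

    tsum1_steps: tuple = (800.0, 900.0, 1000.0)
    tsum2_steps: tuple = (750.0, 850.0, 950.0)
    slatb1_steps: tuple = (0.0026, 0.00305, 0.0035)
    span_steps: tuple = (40.0,)
    tbase_leafage_steps: tuple = (9.0,)
    soils: tuple = ("sandy_loam", "light_loam", "medium_loam")
    sowing_dates: tuple = DEFAULT_SOWING_DATES
    water_modes: tuple = WATER_MODES
    site_years: list = field(default_factory=list)  # (WeatherSeries, year) pairs

    @property
    def n_varieties(self) -> int:
        return (len(self.tsum1_steps) * len(self.tsum2_steps) * len(self.slatb1_steps)
                * len(self.span_steps) * len(self.tbase_leafage_steps))

    def size(self) -> int:
        return (self.n_varieties * len(self.soils) * len(self.sowing_dates)
                * len(self.water_modes) * len(self.site_years))


def build_scenario_grid(grid: GridSpec) -> list[Scenario]:
    """Expand a grid specification into the full scenario list.

    Validates every factor level (crop ranges, soils, sowing dates) and
    requires a nonempty weather site-year list.
    """
    if not grid.site_years:
        raise ConfigurationError("grid.site_years must contain at least one site-year")
    soils = []
    for s in grid.soils:
        if isinstance(s, SoilParameters):
            soils.append(s)
        elif s in SOIL_PRESETS:
            soils.append(SOIL_PRESETS[s])
        else:
            raise ConfigurationError(f"unknown soil preset '{s}'")
    scenarios = []
    i = 0
    for series, year in grid.site_years:
        for tsum1 in grid.tsum1_steps:
            for tsum2 in grid.tsum2_steps:
                for slatb1 in grid.slatb1_steps:
                    for span in grid.span_steps:
                        for tbase in grid.tbase_leafage_steps:
                            crop = CropParameters(
                                tsum1=tsum1, tsum2=tsum2, slatb1=slatb1,
                                span=span, tbase_leafage=tbase,
                            )
                            for soil in soils:
                                for sow in grid.sowing_dates:
                                    for mode in grid.water_modes:
                                        scenarios.append(Scenario(
                                            crop=crop, soil=soil,
                                            management=ManagementConfig(
                                                sowing_date=sow, water_mode=mode),
                                            weather=series, year=year,
                                            scenario_id=f"s{i:06d}",
                                        ))
                                        i += 1
    return scenarios


def run_ensemble(scenarios: list[Scenario], workers: int = 1,
                 thermal: ThermalConfig = ThermalConfig(),
                 season_cutoff_days: int = SEASON_CUTOFF_DAYS) -> list[SimulationTrace]:
    """Simulate every scenario; output order always matches input order.

    Immature traces are returned in place (flagged) and counted in the log;
    callers exclude them when assembling ensembles.
    """
    if not scenarios:
        raise InputError("scenarios must be nonempty")
    if workers > 1:
        from joblib import Parallel, delayed
        traces = Parallel(n_jobs=workers)(
            delayed(run_simulation)(s, thermal, season_cutoff_days=season_cutoff_days)
            for s in scenarios
        )
    else:
        traces = [run_simulation(s, thermal, season_cutoff_days=season_cutoff_days)
                  for s in scenarios]
    n_imm = sum(t.immature for t in traces)
    if n_imm:
        logger.info("ensemble: %d/%d traces immature at cutoff", n_imm, len(traces))
    return traces
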