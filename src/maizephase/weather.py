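"""Synthetic daily weather for the Shandong summer-maize belt.

The generator produces seeded daily series with the statistical structure of
the study region (warm temperate monsoon climate, annual mean temperature
11–14 °C, annual precipitation 550–950 mm):

* temperature — annual sinusoid (peak lagging the solstice) plus an AR(1)
  anomaly;
* precipitation — two-state (wet/dry) Markov occurrence chain with
  gamma-distributed wet-day amounts;
* sunshine duration — fraction of astronomical day length, drawn lower on
  wet days so radiation and rain are negatively coupled;
* global radiation — Angstrom equation from sunshine duration and
  extraterrestrial radiation;
* vapour pressure — saturation pressure at the daily mean temperature times
  a relative-humidity draw (higher on wet days); wind — lognormal.

Series are exchanged on disk in the WOFOST daily column convention
(DAY, IRRAD, TMIN, TMAX, TMEAN, VAP, WIND, RAIN, SNOWDEPTH), with IRRAD in
kJ/m²/day.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError, InputError, WeatherFormatError

__all__ = [
    "WeatherRecord",
    "ClimateProfile",
    "WeatherSeries",
    "generate_weather",
    "angstrom_radiation",
    "extraterrestrial_radiation",
    "day_length",
    "saturation_vapour_pressure",
    "read_weather",
    "write_weather",
    "WEATHER_COLUMNS",
]

#: Mandatory columns of the weather CSV dialect, in canonical order.
WEATHER_COLUMNS = ["DAY", "IRRAD", "TMIN", "TMAX", "TMEAN", "VAP", "WIND", "RAIN"]
#: Optional column; missing values default to zero (no snow in the maize season).
OPTIONAL_COLUMNS = ["SNOWDEPTH"]

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1 (FAO-56)
_DOY_OF_TEMP_PEAK = 201  # July 20: annual temperature maximum lags the solstice
_DOY_OF_RAIN_PEAK = 197  # mid-July: monsoon precipitation maximum


@dataclass(frozen=True)
class WeatherRecord:
    """One day of weather in WOFOST variable convention.

    irrad is global radiation in kJ/m²/day, vap in kPa, wind in m/s,
    rain in mm/day, snowdepth in cm.
    """

    day: dt.date
    irrad: float
    tmin: float
    tmax: float
    tmean: float
    vap: float
    wind: float
    rain: float
    sunshine_hours: float | None = None
    snowdepth: float = 0.0

    def __post_init__(self):
        if not (self.tmin <= self.tmean <= self.tmax):
            raise InputError(
                f"temperature ordering violated on {self.day}: "
                f"tmin={self.tmin} tmean={self.tmean} tmax={self.tmax}"
            )
        for name in ("irrad", "rain", "vap", "wind"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be nonnegative on {self.day}")


@dataclass(frozen=True)
class ClimateProfile:
    """Parameters of the stochastic weather generator.

    Defaults emulate the Shandong summer-maize region: annual mean
    temperature 12.5 °C (band 11–14 °C), annual precipitation ≈700 mm
    (band 550–950 mm), July mean near 27 °C.
    """

    latitude: float = 36.5
    annual_tmean_target: float = 12.5
    annual_precip_target: float = 700.0
    temp_seasonal_amplitude: float = 14.5
    temp_ar1_coeff: float = 0.70
    temp_noise_sd: float = 2.0
    diurnal_range_mean: float = 9.0
    wet_day_prob_wet: float = 0.45  # annual-mean P(wet | previous day wet)
    wet_day_prob_dry: float = 0.22  # annual-mean P(wet | previous day dry)
    #: relative amplitude of the seasonal modulation of the occurrence
    #: probabilities (monsoon climate: wet season peaking mid-July)
    rain_seasonality: float = 0.85
    rain_gamma_shape: float = 1.0
    rain_gamma_scale: float = 5.9  # mm
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    seed: int = 0

    def __post_init__(self):
        if not -90 <= self.latitude <= 90:
            raise ConfigurationError("latitude must lie in [-90, 90]")
        if not 0 < self.angstrom_a + self.angstrom_b <= 1:
            raise ConfigurationError("angstrom_a + angstrom_b must lie in (0, 1]")
        if self.angstrom_a < 0 or self.angstrom_b < 0:
            raise ConfigurationError("angstrom_a and angstrom_b must be nonnegative")
        for name in ("wet_day_prob_wet", "wet_day_prob_dry"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.rain_seasonality <= 1:
            raise ConfigurationError("rain_seasonality must lie in [0, 1]")
        if not 0 <= self.temp_ar1_coeff < 1:
            raise ConfigurationError("temp_ar1_coeff must lie in [0, 1)")
        for name in (
            "temp_noise_sd",
            "temp_seasonal_amplitude",
            "diurnal_range_mean",
            "rain_gamma_shape",
            "rain_gamma_scale",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.annual_precip_target <= 0:
            raise ConfigurationError("annual_precip_target must be positive")

    @classmethod
    def shandong(cls, seed: int = 0) -> "ClimateProfile":
        return cls(seed=seed)


class WeatherSeries:
    """Ordered daily weather records spanning whole calendar years.

    Thin wrapper around a pandas DataFrame in the weather column convention;
    validates monotone gap-free dates and the per-day physical invariants.
    """

    def __init__(self, frame: pd.DataFrame, site_id: str = "site"):
        missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
        if missing:
            raise WeatherFormatError(f"missing mandatory column(s): {', '.join(missing)}")
        frame = frame.copy()
        if "SNOWDEPTH" not in frame.columns:
            frame["SNOWDEPTH"] = 0.0
        frame["SNOWDEPTH"] = frame["SNOWDEPTH"].fillna(0.0)
        frame["DAY"] = pd.to_datetime(frame["DAY"]).dt.date
        days = frame["DAY"].to_numpy()
        if len(days) == 0:
            raise WeatherFormatError("weather series is empty")
        deltas = np.array([(b - a).days for a, b in zip(days[:-1], days[1:])])
        if np.any(deltas <= 0):
            line = int(np.argmax(deltas <= 0)) + 3  # +1 header +1 next row, 1-based
            raise WeatherFormatError("dates not strictly increasing", line=line)
        if np.any(deltas != 1):
            line = int(np.argmax(deltas != 1)) + 3
            raise WeatherFormatError("gap in daily dates", line=line)
        bad = ~(
            (frame["TMIN"] <= frame["TMEAN"])
            & (frame["TMEAN"] <= frame["TMAX"])
        ).to_numpy()
        if bad.any():
            raise WeatherFormatError(
                "tmin <= tmean <= tmax violated", line=int(np.argmax(bad)) + 2
            )
        for col in ("IRRAD", "RAIN", "VAP", "WIND"):
            neg = (frame[col] < 0).to_numpy()
            if neg.any():
                raise WeatherFormatError(
                    f"negative {col}", line=int(np.argmax(neg)) + 2
                )
        self.frame = frame.reset_index(drop=True)
        self.site_id = site_id
        self._index = {d: i for i, d in enumerate(self.frame["DAY"])}

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeatherSeries):
            return NotImplemented
        a = self.frame[WEATHER_COLUMNS + OPTIONAL_COLUMNS]
        b = other.frame[WEATHER_COLUMNS + OPTIONAL_COLUMNS]
        if len(a) != len(b) or not (a["DAY"].to_numpy() == b["DAY"].to_numpy()).all():
            return False
        cols = [c for c in a.columns if c != "DAY"]
        # atol matches the 6-decimal precision of the file dialect
        return bool(np.allclose(a[cols].to_numpy(float), b[cols].to_numpy(float),
                                atol=1e-5))

    @property
    def records(self) -> list[WeatherRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            out.append(
                WeatherRecord(
                    day=row.DAY,
                    irrad=float(row.IRRAD),
                    tmin=float(row.TMIN),
                    tmax=float(row.TMAX),
                    tmean=float(row.TMEAN),
                    vap=float(row.VAP),
                    wind=float(row.WIND),
                    rain=float(row.RAIN),
                    snowdepth=float(row.SNOWDEPTH),
                )
            )
        return out

    @property
    def start(self) -> dt.date:
        return self.frame["DAY"].iloc[0]

    @property
    def end(self) -> dt.date:
        return self.frame["DAY"].iloc[-1]

    @property
    def years(self) -> list[int]:
        """Calendar years fully covered by the series."""
        ys = []
        for y in range(self.start.year, self.end.year + 1):
            if dt.date(y, 1, 1) >= self.start and dt.date(y, 12, 31) <= self.end:
                ys.append(y)
        return ys

    def index_of(self, day: dt.date) -> int:
        try:
            return self._index[day]
        except KeyError:
            raise InputError(f"date {day} not covered by weather series {self.site_id}")

    def covers(self, start: dt.date, end: dt.date) -> bool:
        return start in self._index and end in self._index

    def arrays(self, start: dt.date, n_days: int) -> dict[str, np.ndarray]:
        """Contiguous numpy views of the daily variables from ``start``."""
        i0 = self.index_of(start)
        if i0 + n_days > len(self.frame):
            raise InputError(
                f"weather series {self.site_id} ends before {start} + {n_days} days"
            )
        sl = slice(i0, i0 + n_days)
        out = {
            c: self.frame[c].to_numpy(float)[sl]
            for c in WEATHER_COLUMNS + OPTIONAL_COLUMNS
            if c != "DAY"
        }
        out["DAY"] = self.frame["DAY"].to_numpy()[sl]
        return out


# ---------------------------------------------------------------------------
# Solar geometry and the Angstrom equation
# ---------------------------------------------------------------------------

def _solar_geometry(day_of_year, latitude):
    j = np.asarray(day_of_year, dtype=float)
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * math.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * math.pi * j / 365.0 - 1.39)
    x = np.clip(-math.tan(phi) * np.tan(delta), -1.0, 1.0)
    omega_s = np.arccos(x)
    return dr, delta, omega_s, phi


def extraterrestrial_radiation(day_of_year, latitude: float):
    """Daily extraterrestrial radiation Ra in MJ/m²/day (FAO-56 Eq. 21)."""
    dr, delta, omega_s, phi = _solar_geometry(day_of_year, latitude)
    ra = (
        (24.0 * 60.0 / math.pi)
        * _SOLAR_CONSTANT
        * dr
        * (
            omega_s * math.sin(phi) * np.sin(delta)
            + math.cos(phi) * np.cos(delta) * np.sin(omega_s)
        )
    )
    return np.maximum(ra, 0.0)


def day_length(day_of_year, latitude: float):
    """Astronomical day length N in hours (FAO-56 Eq. 34)."""
    _, _, omega_s, _ = _solar_geometry(day_of_year, latitude)
    return 24.0 / math.pi * omega_s


def angstrom_radiation(sunshine_hours, day_of_year, latitude: float,
                       a: float = 0.25, b: float = 0.50):
    """Global radiation (kJ/m²/day) from sunshine duration.

    Implements Rs = Ra (a + b n/N) with Ra from standard solar geometry and
    N the astronomical day length. ``sunshine_hours`` must satisfy
    0 ≤ n ≤ N; raises :class:`InputError` otherwise.
    """
    n = np.asarray(sunshine_hours, dtype=float)
    big_n = day_length(day_of_year, latitude)
    if np.any(n < 0) or np.any(n > big_n + 1e-9):
        raise InputError("sunshine_hours outside [0, astronomical day length]")
    ra = extraterrestrial_radiation(day_of_year, latitude)
    rs_mj = ra * (a + b * np.where(big_n > 0, n / np.maximum(big_n, 1e-12), 0.0))
    out = np.maximum(rs_mj, 0.0) * 1000.0  # MJ -> kJ
    return float(out) if out.ndim == 0 else out


def saturation_vapour_pressure(t_celsius):
    """Tetens saturation vapour pressure in kPa."""
    t = np.asarray(t_celsius, dtype=float)
    out = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate_weather(profile: ClimateProfile, n_years: int, seed: int | None = None,
                     start_year: int = 1995, site_id: str | None = None) -> WeatherSeries:
    """Generate ``n_years`` whole calendar years of synthetic daily weather.

    Identical (profile, n_years, seed) always yields the identical series.
    ``seed`` overrides ``profile.seed`` when given.
    """
    if n_years < 1:
        raise InputError("n_years must be >= 1")
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(seed)

    days = pd.date_range(
        start=f"{start_year}-01-01", end=f"{start_year + n_years - 1}-12-31", freq="D"
    )
    n = len(days)
    doy = days.dayofyear.to_numpy(float)

    # Daily mean temperature: sinusoid + AR(1) anomaly.
    seasonal = profile.annual_tmean_target + profile.temp_seasonal_amplitude * np.cos(
        2.0 * math.pi * (doy - _DOY_OF_TEMP_PEAK) / 365.25
    )
    eps = rng.normal(0.0, profile.temp_noise_sd, n)
    anomaly = lfilter([1.0], [1.0, -profile.temp_ar1_coeff], eps)
    tmean = seasonal + anomaly

    # Precipitation occurrence: two-state Markov chain whose probabilities
    # follow the monsoon season (wettest mid-July); amounts: gamma.
    u_occ = rng.random(n)
    amounts = (
        rng.gamma(profile.rain_gamma_shape, profile.rain_gamma_scale, n)
        if profile.rain_gamma_scale > 0 and profile.rain_gamma_shape > 0
        else np.zeros(n)
    )
    season = 1.0 + profile.rain_seasonality * np.cos(
        2.0 * math.pi * (doy - _DOY_OF_RAIN_PEAK) / 365.25
    )
    p_w = np.minimum(profile.wet_day_prob_wet * season, 0.95)
    p_d = np.minimum(profile.wet_day_prob_dry * season, 0.95)
    wet = np.zeros(n, dtype=bool)
    prev = False
    for i in range(n):
        prev = u_occ[i] < (p_w[i] if prev else p_d[i])
        wet[i] = prev
    rain = np.where(wet, amounts, 0.0)

    # Sunshine fraction, inversely coupled to rain occurrence.
    u_sun = rng.random(n)
    sun_frac = np.where(wet, 0.05 + 0.35 * u_sun, 0.45 + 0.45 * u_sun)
    big_n = day_length(doy, profile.latitude)
    sunshine = sun_frac * big_n
    irrad = angstrom_radiation(
        sunshine, doy, profile.latitude, profile.angstrom_a, profile.angstrom_b
    )

    # Diurnal range (narrower on wet days), humidity, wind.
    dtr = np.clip(rng.normal(profile.diurnal_range_mean, 1.5, n), 2.0, None)
    dtr = np.where(wet, 0.75 * dtr, dtr)
    u_rh = rng.random(n)
    rh = np.where(wet, 0.70 + 0.25 * u_rh, 0.45 + 0.30 * u_rh)
    vap = rh * saturation_vapour_pressure(tmean)
    wind = rng.lognormal(0.7, 0.45, n)

    frame = pd.DataFrame(
        {
            "DAY": days.date,
            "IRRAD": irrad,
            "TMIN": tmean - 0.5 * dtr,
            "TMAX": tmean + 0.5 * dtr,
            "TMEAN": tmean,
            "VAP": vap,
            "WIND": wind,
            "RAIN": rain,
            "SNOWDEPTH": np.zeros(n),
        }
    )
    return WeatherSeries(frame, site_id=site_id or f"synth-{seed}")


# ---------------------------------------------------------------------------
# I/O in the weather CSV dialect
# ---------------------------------------------------------------------------

def read_weather(path, site_id: str | None = None) -> WeatherSeries:
    """Read a daily weather CSV (header DAY,IRRAD,TMIN,TMAX,TMEAN,VAP,WIND,RAIN[,SNOWDEPTH])."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise WeatherFormatError(f"cannot parse weather file {path}: {exc}") from exc
    missing = [c for c in WEATHER_COLUMNS if c not in frame.columns]
    if missing:
        raise WeatherFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}", line=1
        )
    return WeatherSeries(frame, site_id=site_id or str(path))


def write_weather(series: WeatherSeries, path) -> None:
    """Write a series in the weather CSV dialect (round-trips with read_weather)."""
    out = series.frame[WEATHER_COLUMNS + OPTIONAL_COLUMNS].copy()
    out["DAY"] = [d.isoformat() for d in out["DAY"]]
    out.to_csv(path, index=False, float_format="%.6f")
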