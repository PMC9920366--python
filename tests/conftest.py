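"""Shared fixtures: small deterministic ensembles reused across test modules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from maizephase import (ClimateProfile, GridSpec, Scenario, SplitSpec,
                        build_feature_matrix, build_scenario_grid,
                        calibrate_thresholds, generate_weather, run_ensemble,
                        segment_trace)
from maizephase.weather import WeatherSeries


def constant_weather(tmean: float = 20.0, years=(2001, 2002), irrad: float = 18000.0,
                     rain: float = 0.0, dtr: float = 8.0, site_id: str = "const"):
    """Whole calendar years of perfectly constant weather (analytic oracle)."""
    days = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    n = len(days)
    frame = pd.DataFrame({
        "DAY": days.date,
        "IRRAD": np.full(n, irrad),
        "TMIN": np.full(n, tmean - dtr / 2),
        "TMAX": np.full(n, tmean + dtr / 2),
        "TMEAN": np.full(n, tmean),
        "VAP": np.full(n, 1.5),
        "WIND": np.full(n, 2.0),
        "RAIN": np.full(n, rain),
    })
    return WeatherSeries(frame, site_id=site_id)


@pytest.fixture(scope="session")
def const20():
    return constant_weather(20.0)


@pytest.fixture(scope="session")
def shandong_weather():
    """Six years of default-profile synthetic weather."""
    return generate_weather(ClimateProfile(), n_years=6, seed=7)


@pytest.fixture(scope="session")
def thresholds(shandong_weather):
    return calibrate_thresholds([shandong_weather])


@pytest.fixture(scope="session")
def small_grid(shandong_weather):
    """Reduced variety grid over two synthetic years (216 scenarios)."""
    return GridSpec(
        tsum1_steps=(800.0, 900.0, 1000.0),
        tsum2_steps=(750.0, 950.0),
        slatb1_steps=(0.0026, 0.0035),
        site_years=[(shandong_weather, y) for y in shandong_weather.years[:2]],
    )


@pytest.fixture(scope="session")
def small_ensemble(small_grid):
    scenarios = build_scenario_grid(small_grid)
    traces = run_ensemble(scenarios)
    return scenarios, traces


@pytest.fixture(scope="session")
def small_bounds(small_ensemble, thresholds):
    _, traces = small_ensemble
    return [segment_trace(t, thresholds) for t in traces]


@pytest.fixture(scope="session")
def small_matrix(small_ensemble, small_bounds):
    scenarios, traces = small_ensemble
    return build_feature_matrix(scenarios, traces, small_bounds)
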