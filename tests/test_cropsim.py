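"""Reduced crop simulator: development, water balance, growth dynamics."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from maizephase import (CropParameters, GridSpec, ManagementConfig,
                        PhotoperiodConfig, Scenario, SoilParameters,
                        SOIL_PRESETS, advance_dvs, build_scenario_grid,
                        daily_step, run_ensemble, run_simulation)
from maizephase.cropsim import DailyState
from maizephase.errors import ConfigurationError, InputError, SequencingError
from maizephase.weather import WeatherRecord

from conftest import constant_weather


def make_scenario(weather, year=2001, mode="potential", crop=None,
                  soil=None, sowing="06-01", sid="s0"):
    return Scenario(
        crop=crop or CropParameters(),
        soil=soil or SOIL_PRESETS["light_loam"],
        management=ManagementConfig(sowing_date=sowing, water_mode=mode),
        weather=weather, year=year, scenario_id=sid,
    )


class TestParameters:
    @pytest.mark.parametrize("field,value", [
        ("tsum1", 700.0), ("tsum1", 1100.0), ("tsum2", 700.0),
        ("slatb1", 0.005), ("span", 20.0), ("tbase_leafage", 12.0),
    ])
    def test_calibration_range_enforced(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            CropParameters(**{field: value})

    def test_partition_fractions_must_sum_to_one(self):
        bad = ((0.0, 0.5, 0.2, 0.0, 0.2), (2.0, 0, 0, 1, 0))
        with pytest.raises(ConfigurationError):
            CropParameters(partition_table=bad)

    def test_soil_moisture_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            SoilParameters(smw=0.30, sm0=0.34, smfcf=0.28)

    def test_photoperiod_factor_clamped(self):
        f = PhotoperiodConfig(enabled=True, p_actual=20, p_critical=12,
                              p_optimal=16).factor()
        assert f == 1.0
        f = PhotoperiodConfig(enabled=True, p_actual=10, p_critical=12,
                              p_optimal=16).factor()
        assert f == 0.0


class TestDevelopment:
    def test_linear_accumulation_to_anthesis(self):
        crop = CropParameters(tsum1=900)
        state = DailyState(date=dt.date(2001, 7, 1), dvs=0.0, lai=1, tra=0,
                          sm=0.2, w_leaf=10, w_stem=10, w_storage=0, w_root=10,
                          stress=1)
        dvs = 0.0
        for _ in range(45):  # 45 days x 10 degC d = 450 since emergence
            state.dvs = dvs
            dvs = advance_dvs(state, 10.0, crop)
        assert dvs == pytest.approx(0.5)

    def test_dvs_is_one_at_tsum1_and_two_at_tsum1_plus_tsum2(self):
        crop = CropParameters(tsum1=900, tsum2=800)
        state = DailyState(date=dt.date(2001, 7, 1), dvs=0.0, lai=1, tra=0,
                          sm=0.2, w_leaf=10, w_stem=10, w_storage=0, w_root=10,
                          stress=1)
        dvs = 0.0
        for i in range(180):
            state.dvs = dvs
            dvs = advance_dvs(state, 10.0, crop)
            if i == 89:
                assert dvs == pytest.approx(1.0)  # 900/10 days
        assert dvs == 2.0  # capped at maturity after 1700 degC d

    def test_negative_thermal_time_rejected(self):
        state = DailyState(date=dt.date(2001, 7, 1), dvs=0.0, lai=1, tra=0,
                          sm=0.2, w_leaf=10, w_stem=10, w_storage=0, w_root=10,
                          stress=1)
        with pytest.raises(InputError):
            advance_dvs(state, -1.0, CropParameters())


class TestDailyStep:
    def _state(self, sm=0.28, lai=2.0):
        return DailyState(date=dt.date(2001, 7, 1), dvs=0.5, lai=lai, tra=0.0,
                          sm=sm, w_leaf=500, w_stem=400, w_storage=0.0,
                          w_root=200, stress=1.0)

    def _record(self, day=dt.date(2001, 7, 2), irrad=18000.0, rain=0.0):
        return WeatherRecord(day=day, irrad=irrad, tmin=20, tmax=30, tmean=25,
                             vap=2.0, wind=2.0, rain=rain)

    def test_potential_mode_never_stressed(self, shandong_weather):
        scen = make_scenario(shandong_weather, mode="potential")
        out = daily_step(self._state(), self._record(), scen)
        assert out.stress == 1.0
        assert out.sm == scen.soil.smfcf

    def test_zero_radiation_day_no_growth_only_senescence(self, shandong_weather):
        scen = make_scenario(shandong_weather, mode="potential")
        state = self._state()
        out = daily_step(state, self._record(irrad=0.0), scen)
        total_before = state.w_leaf + state.w_stem + state.w_storage + state.w_root
        total_after = out.w_leaf + out.w_stem + out.w_storage + out.w_root
        assert total_after <= total_before  # only senescence may remove mass
        assert out.w_stem == state.w_stem and out.w_storage == state.w_storage

    def test_rainless_days_soil_drying_bounded_by_wilting_point(self, shandong_weather):
        scen = make_scenario(shandong_weather, mode="water_limited")
        state = self._state(sm=scen.soil.smfcf)
        day = dt.date(2001, 7, 1)
        sms = []
        for i in range(10):
            rec = self._record(day=day + dt.timedelta(days=i + 1))
            state = daily_step(state, rec, scen)
            sms.append(state.sm)
        assert all(b <= a + 1e-12 for a, b in zip(sms[:-1], sms[1:]))
        assert all(s >= scen.soil.smw - 1e-12 for s in sms)

    def test_weather_gap_rejected(self, shandong_weather):
        scen = make_scenario(shandong_weather)
        with pytest.raises(SequencingError):
            daily_step(self._state(), self._record(day=dt.date(2001, 7, 5)), scen)


class TestRunSimulation:
    def test_deterministic_rerun_identical(self, shandong_weather):
        scen = make_scenario(shandong_weather, year=shandong_weather.years[0])
        a = run_simulation(scen)
        b = run_simulation(scen)
        assert np.array_equal(a.dvs, b.dvs)
        assert np.array_equal(a.w_storage, b.w_storage)
        assert a.yield_final == b.yield_final

    def test_emergence_day_six_at_constant_twenty_degrees(self, const20):
        scen = make_scenario(const20, year=2001)
        trace = run_simulation(scen)
        # ceil(70 / 12) = 6 days after the June 1 sowing
        assert trace.emergence_date == dt.date(2001, 6, 7)

    def test_water_limited_yield_never_exceeds_potential(self, shandong_weather):
        for year in shandong_weather.years[:3]:
            for sowing in ("06-01", "06-19"):
                pot = run_simulation(make_scenario(
                    shandong_weather, year, "potential", sowing=sowing))
                wl = run_simulation(make_scenario(
                    shandong_weather, year, "water_limited", sowing=sowing))
                assert wl.yield_final <= pot.yield_final + 1e-9

    def test_dvs_monotone_and_anthesis_at_tsum1_crossing(self, small_ensemble):
        scenarios, traces = small_ensemble
        for scen, trace in zip(scenarios, traces):
            dvs = trace.dvs
            assert np.all(np.diff(dvs) >= -1e-12)
            cum = np.cumsum(np.clip(trace.tmean - 8.0, 0.0, 21.0))
            crossing = np.searchsorted(cum, scen.crop.tsum1)
            reached = np.nonzero(dvs >= 1.0)[0]
            if len(reached):
                assert abs(int(reached[0]) - int(crossing)) <= 1

    def test_water_balance_closes_exactly(self, small_ensemble):
        _, traces = small_ensemble
        for trace in traces:
            if len(trace) < 2:
                continue
            delta = np.diff(trace.storage_mm)
            flux = (trace.rain + trace.irrigation - trace.tra
                    - trace.soil_evap - trace.drainage)[1:]
            assert np.max(np.abs(delta - flux)) <= 1e-6

    def test_lai_rises_then_declines(self, small_ensemble):
        _, traces = small_ensemble
        for trace in traces:
            if not trace.mature:
                continue
            lai = trace.lai
            peak = int(np.argmax(lai))
            assert lai[peak] > lai[0]
            after = lai[peak:]
            # senescence phase: no rise of more than 2% of the peak
            assert np.all(np.diff(after) <= 0.02 * lai[peak])
            assert after[-1] < 0.75 * lai[peak]

    def test_storage_biomass_zero_before_onset(self, small_ensemble):
        _, traces = small_ensemble
        for trace in traces:
            pre = trace.w_storage[trace.dvs < 0.95]
            assert np.all(pre == 0.0)

    def test_weather_must_cover_the_season(self):
        short = constant_weather(20.0, years=(2001, 2001))
        scen = make_scenario(short, year=2001, sowing="06-19")
        with pytest.raises(InputError, match="cover"):
            run_simulation(scen, season_cutoff_days=300)

    def test_more_rain_never_lowers_median_water_limited_yield(
            self, shandong_weather):
        grid = GridSpec(tsum1_steps=(900.0,), tsum2_steps=(850.0,),
                        slatb1_steps=(0.003,), water_modes=("water_limited",),
                        site_years=[(shandong_weather, y)
                                    for y in shandong_weather.years])
        scenarios = build_scenario_grid(grid)
        base = [run_simulation(s).yield_final for s in scenarios]
        wet_frame = shandong_weather.frame.copy()
        wet_frame["RAIN"] = wet_frame["RAIN"] * 1.5
        from maizephase.weather import WeatherSeries
        wetter = WeatherSeries(wet_frame, site_id="wetter")
        wet = [run_simulation(dataclasses.replace(s, weather=wetter)).yield_final
               for s in scenarios]
        assert np.median(wet) >= np.median(base) - 1e-9


class TestGridAndEnsemble:
    def test_grid_cardinality_arithmetic(self, shandong_weather):
        site_years = [(shandong_weather, y) for y in shandong_weather.years[:5]]
        site_years = site_years * 2  # 10 site-year slots
        grid = GridSpec(
            tsum1_steps=tuple(np.linspace(800, 1000, 5)),
            tsum2_steps=tuple(np.linspace(750, 950, 5)),
            slatb1_steps=(0.003,), span_steps=(40.0,),
            tbase_leafage_steps=(9.0,), site_years=site_years,
        )
        scenarios = build_scenario_grid(grid)
        assert len(scenarios) == 4500
        assert len({s.scenario_id for s in scenarios}) == 4500

    def test_grid_covers_all_three_loam_types(self, small_grid):
        scenarios = build_scenario_grid(small_grid)
        assert {s.soil.loam_type for s in scenarios} == {
            "sandy_loam", "light_loam", "medium_loam"}

    def test_empty_weather_rejected(self):
        with pytest.raises(ConfigurationError):
            build_scenario_grid(GridSpec(site_years=[]))

    def test_out_of_range_variety_step_rejected(self, shandong_weather):
        grid = GridSpec(tsum1_steps=(700.0,),
                        site_years=[(shandong_weather, shandong_weather.years[0])])
        with pytest.raises(ConfigurationError):
            build_scenario_grid(grid)

    def test_workers_do_not_change_results(self, shandong_weather):
        grid = GridSpec(tsum1_steps=(900.0,), tsum2_steps=(850.0,),
                        slatb1_steps=(0.003,),
                        site_years=[(shandong_weather, shandong_weather.years[0])])
        scenarios = build_scenario_grid(grid)
        seq = run_ensemble(scenarios, workers=1)
        par = run_ensemble(scenarios, workers=2)
        for a, b in zip(seq, par):
            assert a.scenario_id == b.scenario_id
            assert np.array_equal(a.w_storage, b.w_storage)

    def test_ensemble_yields_span_low_and_high(self, small_ensemble):
        _, traces = small_ensemble
        ys = np.array([t.yield_final for t in traces if not t.immature])
        assert ys.std() > 0
        assert ys.max() > 1.5 * ys.min()
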