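"""Unit and property tests for the reduced crop growth model."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pytest

from cropassim.crop_model import (
    CropParameters,
    CropState,
    ParameterTable,
    WeatherSeries,
    afgen_interp,
    extract_lai,
    run_simulation,
    step_growth,
    step_phenology,
)
from cropassim.errors import (
    ConfigurationError,
    IncompleteSeasonError,
    OutOfRangeDateError,
)


def constant_weather(n, tmean, radiation, start=dt.date(2015, 11, 1)):
    dates = tuple(start + dt.timedelta(days=i) for i in range(n))
    return WeatherSeries(
        dates=dates, tmean=np.full(n, float(tmean)), radiation=np.full(n, float(radiation))
    )


class TestAfgen:
    @pytest.mark.parametrize(
        "knots, dvs, expected",
        [
            (((0.0, 0.002), (0.5, 0.002)), 0.25, 0.002),       # constant table
            (((0.0, 0.0010), (0.5, 0.0020)), 0.25, 0.0015),    # linear midpoint
            (((1.0, 38.83), (1.3, 38.83)), 2.0, 38.83),        # clamped right
            (((1.0, 38.83), (1.3, 45.0)), 0.2, 38.83),         # clamped left
            (((0.0, 1.0),), 1.7, 1.0),                         # single knot
        ],
    )
    def test_interpolation(self, knots, dvs, expected):
        assert afgen_interp(ParameterTable(knots), dvs) == pytest.approx(expected, rel=1e-12)

    def test_empty_table_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ParameterTable(())

    @pytest.mark.parametrize(
        "knots",
        [((0.5, 1.0), (0.5, 2.0)), ((1.0, 1.0), (0.5, 2.0)), ((0.0, -1.0),),
         ((0.0, float("nan")),)],
    )
    def test_invalid_tables_rejected(self, knots):
        with pytest.raises(ConfigurationError):
            ParameterTable(knots)

    def test_non_finite_dvs_rejected(self):
        table = ParameterTable(((0.0, 1.0), (1.0, 2.0)))
        with pytest.raises(ConfigurationError):
            afgen_interp(table, float("nan"))


class TestPhenology:
    def test_zero_effective_temperature_leaves_dvs_unchanged(self, base_params):
        state = CropState(dvs=0.4, emerged=True)
        step_phenology(state, base_params.t_base, base_params)
        assert state.dvs == 0.4

    def test_dvs_increment_matches_thermal_time_ratio(self, base_params):
        params = replace(base_params, tsum1=1000.0)
        state = CropState(dvs=0.0, emerged=True)
        step_phenology(state, params.t_base + 10.0, params)
        assert state.dvs == pytest.approx(0.01, abs=1e-15)

    def test_anthesis_reached_after_exactly_tsum1_over_eff_days(self, base_params):
        params = replace(base_params, tsum1=1000.0)
        state = CropState(dvs=0.0, emerged=True)
        for day in range(100):
            assert state.dvs < 1.0
            step_phenology(state, params.t_base + 10.0, params)
        assert state.dvs == pytest.approx(1.0, abs=1e-9)

    def test_pre_emergence_accumulates_toward_tsumem(self, base_params):
        params = replace(base_params, tsumem=50.0)
        state = CropState()
        step_phenology(state, params.t_base + 30.0, params)
        assert not state.emerged
        step_phenology(state, params.t_base + 30.0, params)
        assert state.emerged
        assert state.lai == params.lai_init
        assert state.w_leaf == pytest.approx(params.lai_init / params.slatb(0.0))


class TestGrowth:
    def test_zero_lai_intercepts_no_light(self, base_params):
        state = CropState(emerged=True, dvs=0.5, lai=0.0, w_leaf=0.0)
        before = (state.w_leaf, state.w_stem, state.w_storage, state.w_root)
        step_growth(state, 15.0, 20.0, base_params)
        assert (state.w_leaf, state.w_stem, state.w_storage, state.w_root) == before
        assert state.lai == 0.0

    def test_negative_net_assimilate_never_shrinks_pools_except_senescence(self, base_params):
        # huge maintenance load, no light
        state = CropState(emerged=True, dvs=0.5, lai=2.0, w_leaf=1000.0, w_stem=500.0)
        step_growth(state, 25.0, 0.0, base_params)
        assert state.w_leaf == 1000.0  # pre-anthesis: no senescence either
        assert state.w_stem == 500.0
        assert state.w_storage >= 0.0

    def test_doubling_amax_doubles_gross_assimilation(self, base_params):
        params = replace(
            base_params, maint_coefs={o: 0.0 for o in ("leaf", "stem", "storage", "root")}
        )
        gains = []
        for factor in (1.0, 2.0):
            sens = params.sensitive_values()
            p = params.with_sensitive(
                {"amaxtb1": sens["amaxtb1"] * factor, "amaxtb1.3": sens["amaxtb1.3"] * factor}
            )
            state = CropState(emerged=True, dvs=0.3, lai=0.1, w_leaf=50.0)
            total0 = state.w_leaf + state.w_stem + state.w_storage + state.w_root
            step_growth(state, 15.0, 20.0, p)
            gains.append(state.w_leaf + state.w_stem + state.w_storage + state.w_root - total0)
        assert gains[1] == pytest.approx(2.0 * gains[0], rel=1e-9)

    def test_senescence_limited_to_available_pool(self, base_params):
        params = replace(base_params, rdr_base=5.0)  # absurdly fast death
        state = CropState(emerged=True, dvs=1.9, lai=0.5, w_leaf=100.0)
        step_growth(state, 15.0, 10.0, params)
        assert state.lai >= 0.0
        assert state.w_leaf >= 0.0


class TestRunSimulation:
    def test_deterministic(self, base_params, weather16, design16):
        a = run_simulation(base_params, weather16, design16.sowing_date)
        b = run_simulation(base_params, weather16, design16.sowing_date)
        assert np.array_equal(a.lai, b.lai)
        assert np.array_equal(a.dvs, b.dvs)
        assert np.array_equal(a.w_storage, b.w_storage)

    def test_state_invariants(self, localized_trajectory):
        t = localized_trajectory
        assert np.all(np.diff(t.dvs) >= 0)
        assert np.all(t.lai >= 0)
        for arr in (t.w_leaf, t.w_stem, t.w_storage, t.w_root):
            assert np.all(arr >= 0)
        np.testing.assert_array_equal(t.tagp, t.w_leaf + t.w_stem + t.w_storage)

    def test_anthesis_crossed_once(self, localized_trajectory):
        crossings = np.sum((localized_trajectory.dvs[:-1] < 1.0)
                           & (localized_trajectory.dvs[1:] >= 1.0))
        assert crossings == 1

    def test_yield_equals_storage_at_maturity(self, localized_trajectory):
        t = localized_trajectory
        assert t.maturity_date is not None
        assert t.yield_kg_per_hm2 == t.w_storage[t.index_of(t.maturity_date)]

    def test_storage_nondecreasing_until_maturity(self, localized_trajectory):
        t = localized_trajectory
        until = t.index_of(t.maturity_date)
        assert np.all(np.diff(t.w_storage[: until + 1]) >= 0)

    def test_single_lai_peak_in_anthesis_window(self, localized_trajectory):
        t = localized_trajectory
        smoothed = np.convolve(t.lai, np.ones(3) / 3.0, mode="valid")
        interior = (smoothed[1:-1] > smoothed[:-2]) & (smoothed[1:-1] > smoothed[2:])
        # ignore the flat zero stretch before emergence
        assert int(np.sum(interior & (smoothed[1:-1] > 0.1))) == 1
        peak_dvs = t.dvs[int(np.argmax(t.lai))]
        assert 0.8 <= peak_dvs <= 1.2

    def test_short_weather_raises_incomplete_season(self, base_params, weather16, design16):
        short = WeatherSeries(
            dates=weather16.dates[:120],
            tmean=weather16.tmean[:120],
            radiation=weather16.radiation[:120],
        )
        with pytest.raises(IncompleteSeasonError) as err:
            run_simulation(base_params, short, design16.sowing_date)
        partial = err.value.partial_trajectory
        assert partial is not None
        assert not partial.complete
        assert partial.maturity_date is None

    def test_tiny_tsum2_means_maturity_right_after_anthesis(
        self, base_params, weather16, design16
    ):
        params = replace(base_params, tsum2=0.001)
        t = run_simulation(params, weather16, design16.sowing_date)
        assert t.maturity_date is not None
        assert (t.maturity_date - t.anthesis_date).days <= 1
        assert t.yield_kg_per_hm2 == t.w_storage[t.index_of(t.maturity_date)]

    def test_sowing_outside_weather_is_configuration_error(self, base_params, weather16):
        with pytest.raises(ConfigurationError):
            run_simulation(base_params, weather16, dt.date(2010, 1, 1))


class TestClosedFormGrowthLimit:
    def test_pre_anthesis_lai_matches_independent_recurrence(self, base_params):
        """With constant weather, zero respiration and zero senescence, the
        model's pre-anthesis LAI must match a direct scratch re-computation
        of the daily recurrence to 1e-8 relative error over 10 days."""
        params = replace(
            base_params,
            maint_coefs={o: 0.0 for o in ("leaf", "stem", "storage", "root")},
            rdr_base=0.0,
            tsumem=5.0,
        )
        tmean, rad = 15.0, 20.0
        weather = constant_weather(12, tmean, rad)
        traj = run_simulation(params, weather, weather.dates[0], require_maturity=False)
        i0 = traj.index_of(traj.emergence_date)

        # independent recurrence (scratch implementation of the daily budget)
        ch2o = 30.0 / 44.0
        lai = params.lai_init
        dvs = 0.0
        expected = [lai]
        eff = tmean - params.t_base
        for _ in range(10):
            amax = params.amaxtb(dvs)
            f_rad = min(1.0, rad / params.r_ref)
            gross = amax * params.f_day * (1.0 - np.exp(-params.k_ext * lai)) * f_rad * ch2o
            growth = params.cvs * gross
            lai = lai + params.slatb(dvs) * growth * params.partition_tables["leaf"](dvs)
            dvs = dvs + eff / params.tsum1
            expected.append(lai)

        got = traj.lai[i0 : i0 + 11]
        np.testing.assert_allclose(got, expected, rtol=1e-8)


class TestSensitivityDirections:
    @pytest.mark.parametrize("key", ["slatb0", "slatb0.5", "slatb2"])
    def test_more_specific_leaf_area_never_lowers_peak_lai(
        self, base_params, weather16, design16, key
    ):
        ref = run_simulation(base_params, weather16, design16.sowing_date)
        bumped = base_params.with_sensitive(
            {key: base_params.sensitive_values()[key] * 1.10}
        )
        alt = run_simulation(bumped, weather16, design16.sowing_date)
        assert alt.lai.max() >= ref.lai.max() - 1e-9

    @pytest.mark.parametrize("key", ["amaxtb1", "amaxtb1.3"])
    def test_more_assimilation_never_lowers_yield(
        self, base_params, weather16, design16, key
    ):
        ref = run_simulation(base_params, weather16, design16.sowing_date)
        bumped = base_params.with_sensitive(
            {key: base_params.sensitive_values()[key] * 1.10}
        )
        alt = run_simulation(bumped, weather16, design16.sowing_date)
        assert alt.yield_kg_per_hm2 >= ref.yield_kg_per_hm2 - 1e-9


class TestExtractLai:
    def test_emergence_date_gives_initial_lai(self, localized_trajectory, base_params):
        got = extract_lai(localized_trajectory, [localized_trajectory.emergence_date])
        assert got[0] == base_params.lai_init

    def test_five_dates_give_five_values(self, localized_trajectory, design16):
        assert len(extract_lai(localized_trajectory, design16.observation_dates)) == 5

    def test_duplicate_dates_give_identical_values(self, localized_trajectory, design16):
        d = design16.observation_dates[2]
        got = extract_lai(localized_trajectory, [d, d])
        assert got[0] == got[1]

    def test_out_of_range_date_names_the_date(self, localized_trajectory):
        with pytest.raises(OutOfRangeDateError, match="1999-01-01"):
            extract_lai(localized_trajectory, [dt.date(1999, 1, 1)])


class TestParameterValidation:
    def test_partition_fractions_must_sum_to_one(self, base_params):
        bad = dict(base_params.partition_tables)
        bad["leaf"] = ParameterTable(((0.0, 0.9), (2.0, 0.9)))
        with pytest.raises(ConfigurationError, match="sum"):
            replace(base_params, partition_tables=bad)

    @pytest.mark.parametrize("field_name, value", [
        ("cvs", 0.0), ("cvs", 1.5), ("tsum1", -5.0), ("lai_init", 0.0),
    ])
    def test_scalar_bounds(self, base_params, field_name, value):
        with pytest.raises(ConfigurationError):
            replace(base_params, **{field_name: value})

    def test_yaml_round_trip(self, base_params, tmp_path):
        path = tmp_path / "params.yaml"
        base_params.to_yaml(path)
        again = CropParameters.from_yaml(path)
        assert again == base_params


class TestWeatherSeries:
    def test_csv_round_trip(self, weather16, tmp_path):
        path = tmp_path / "weather.csv"
        weather16.to_csv(path)
        again = WeatherSeries.from_csv(path)
        assert again.dates == weather16.dates
        np.testing.assert_allclose(again.tmean, weather16.tmean, rtol=0, atol=1e-9)

    def test_gap_in_dates_rejected(self, weather16):
        dates = weather16.dates[:10] + weather16.dates[11:21]
        with pytest.raises(ConfigurationError, match="consecutive"):
            WeatherSeries(dates=dates, tmean=np.zeros(20), radiation=np.zeros(20))

    def test_negative_radiation_rejected(self):
        with pytest.raises(ConfigurationError, match="radiation"):
            constant_weather(5, 10.0, -1.0)
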