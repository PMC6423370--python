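"""Microclimate analytics: IDW grid interpolation, heat-map series framing,
leave-one-out validation, the Smith-Period detector, and correlation."""

import warnings
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenosync.analytics import (
    AlignmentError,
    InsufficientSensorsError,
    NoDataError,
    detect_smith_periods,
    heatmap_series,
    interpolate_plot_grid,
    loo_validation,
    sensor_correlation,
    smith_day_qualifies,
)
from phenosync.models import RiskPeriod

from conftest import dt, make_field, reading

AT = dt(2017, 5, 1, 12)

# a 1x3 strip: sensors on the two ends, target plot in the middle
LINE = {(0, 0): "dev-a", (0, 2): "dev-b"}


def line_field(values: dict[str, float], grid=(1, 3), monitored=LINE):
    store, _ = make_field(grid=grid, monitored=monitored)
    for device_id, v in values.items():
        store.record_readings([reading(device_id, 12, v)])
    return store


class TestInterpolation:
    def test_equidistant_sensors_give_midpoint(self):
        store = line_field({"dev-a": 10.0, "dev-b": 20.0})
        grid = interpolate_plot_grid(store, "exp", "ambient_temp_C", AT)
        assert grid.values[0, 1] == pytest.approx(15.0)
        assert list(grid.measured_mask[0]) == [True, False, True]

    def test_exact_at_sensor_plots(self):
        store, _ = make_field()
        store.record_readings(
            [reading("dev-a", h, 10.0 + h) for h in range(10, 15)]
        )
        store.record_readings([reading("dev-b", 12, 99.0)])
        grid = interpolate_plot_grid(store, "exp", "ambient_temp_C", AT)
        windowed_mean = np.mean([10.0 + h for h in range(10, 15)])
        assert grid.values[0, 0] == pytest.approx(windowed_mean)
        assert grid.values[0, 2] == pytest.approx(99.0)

    def test_constant_field_fills_constant(self):
        store, monitored = make_field()
        for device_id in monitored.values():
            store.record_readings([reading(device_id, 12, 7.5)])
        grid = interpolate_plot_grid(store, "exp", "ambient_temp_C", AT)
        assert np.allclose(grid.values, 7.5)
        assert grid.measured_mask.sum() == 3

    def test_no_readings_anywhere_raises(self):
        store, _ = make_field()
        with pytest.raises(NoDataError):
            interpolate_plot_grid(store, "exp", "ambient_temp_C", AT)

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.floats(-40, 60, allow_nan=False), min_size=3, max_size=3
        ),
        shift=st.floats(-50, 50, allow_nan=False),
    )
    def test_bounded_and_translation_equivariant(self, values, shift):
        """Interpolated cells stay inside [min, max] of the measured values,
        and adding a constant to all sensors adds it everywhere."""
        names = ["dev-a", "dev-b", "dev-c"]
        store = line_field(
            dict(zip(names, values)), grid=(3, 3),
            monitored={(0, 0): "dev-a", (0, 2): "dev-b", (2, 1): "dev-c"},
        )
        grid = interpolate_plot_grid(store, "exp", "ambient_temp_C", AT)
        assert grid.values.min() >= min(values) - 1e-9
        assert grid.values.max() <= max(values) + 1e-9
        shifted_store = line_field(
            {n: v + shift for n, v in zip(names, values)}, grid=(3, 3),
            monitored={(0, 0): "dev-a", (0, 2): "dev-b", (2, 1): "dev-c"},
        )
        shifted = interpolate_plot_grid(shifted_store, "exp", "ambient_temp_C", AT)
        assert np.allclose(shifted.values, grid.values + shift, atol=1e-8)


class TestHeatmapSeries:
    def seeded_store(self):
        store = line_field({"dev-a": 10.0, "dev-b": 20.0})
        # give every frame instant some data
        for device_id in ("dev-a", "dev-b"):
            store.record_readings(
                [reading(device_id, 24 * d + 12, 15.0) for d in range(1, 60)]
            )
        return store

    def test_56_day_span_at_14_day_interval_gives_5_frames(self):
        store = self.seeded_store()
        frames = heatmap_series(
            store, "exp", "ambient_temp_C", AT, AT + timedelta(days=56),
            interval_days=14,
        )
        assert len(frames) == 5
        assert [f.at for f in frames] == [
            AT + timedelta(days=14 * i) for i in range(5)
        ]

    def test_span_shorter_than_interval_gives_one_frame(self):
        store = self.seeded_store()
        frames = heatmap_series(
            store, "exp", "ambient_temp_C", AT, AT + timedelta(days=3),
        )
        assert len(frames) == 1 and frames[0].at == AT

    def test_daily_interval_over_three_days_gives_four_frames(self):
        store = self.seeded_store()
        frames = heatmap_series(
            store, "exp", "ambient_temp_C", AT, AT + timedelta(days=3),
            interval_days=1,
        )
        assert len(frames) == 4

    def test_frame_without_data_is_explicit_empty_marker(self):
        store = line_field({"dev-a": 10.0, "dev-b": 20.0})  # data on day 0 only
        frames = heatmap_series(
            store, "exp", "ambient_temp_C", AT, AT + timedelta(days=28),
            interval_days=14,
        )
        assert [f.empty for f in frames] == [False, True, True]


class TestLooValidation:
    def test_uniform_field_has_zero_rmse(self):
        store, monitored = make_field()
        for device_id in monitored.values():
            store.record_readings([reading(device_id, 12, 5.0)])
        table, rmse = loo_validation(store, "exp", "ambient_temp_C", AT)
        assert rmse == pytest.approx(0.0)
        assert np.allclose(table["error"], 0.0)

    def test_single_sensor_is_insufficient(self):
        store = line_field({"dev-a": 10.0})
        with pytest.raises(InsufficientSensorsError):
            loo_validation(store, "exp", "ambient_temp_C", AT)

    def test_three_sensors_on_a_line_match_hand_computed_idw(self):
        # sensors at cols 0,1,2 with 10,15,20; power-2 IDW, distance 1 and 2:
        #  col0 <- (15/1 + 20/4) / (1 + 1/4) = 16.0
        #  col1 <- (10/1 + 20/1) / 2        = 15.0
        #  col2 <- (15/1 + 10/4) / (1 + 1/4) = 14.0
        monitored = {(0, 0): "dev-a", (0, 1): "dev-b", (0, 2): "dev-c"}
        store = line_field(
            {"dev-a": 10.0, "dev-b": 15.0, "dev-c": 20.0},
            grid=(1, 3), monitored=monitored,
        )
        table, rmse = loo_validation(store, "exp", "ambient_temp_C", AT)
        by_col = table.set_index("col")["predicted"]
        assert by_col[0] == pytest.approx(16.0)
        assert by_col[1] == pytest.approx(15.0)
        assert by_col[2] == pytest.approx(14.0)
        expected_rmse = np.sqrt(np.mean([6.0**2, 0.0, 6.0**2]))
        assert rmse == pytest.approx(expected_rmse)

    def test_rmse_shrinks_as_field_smooths(self):
        """Spatial roughness drives LOO error: flattening the field toward
        its mean must drive RMSE toward zero."""
        rng = np.random.default_rng(0)
        base = {d: 15.0 for d in ("dev-a", "dev-b", "dev-c")}
        rough = {d: 15.0 + float(rng.uniform(-5, 5)) for d in base}
        rmses = []
        for alpha in (1.0, 0.3, 0.0):
            values = {d: 15.0 + alpha * (rough[d] - 15.0) for d in rough}
            store = line_field(values, grid=(3, 3),
                               monitored={(0, 0): "dev-a", (0, 2): "dev-b",
                                          (2, 1): "dev-c"})
            rmses.append(loo_validation(store, "exp", "ambient_temp_C", AT)[1])
        assert rmses[0] > rmses[1] > rmses[2] == pytest.approx(0.0)


def hourly_series(day_values, start=dt(2017, 6, 1)):
    """Build aligned hourly temp/RH series from per-day (temp, rh_hours)
    prescriptions: each day has constant temp and ``rh_hours`` hours at 95%
    RH (the rest at 50%)."""
    temps, rhs, idx = [], [], []
    for d, (temp, rh_hours) in enumerate(day_values):
        for h in range(24):
            idx.append(start + timedelta(days=d, hours=h))
            temps.append(temp)
            rhs.append(95.0 if h < rh_hours else 50.0)
    index = pd.DatetimeIndex(idx)
    return pd.Series(temps, index=index), pd.Series(rhs, index=index)


def oracle_periods(qualifies: list[bool], start: date):
    """Brute force: enumerate all maximal runs of qualifying days >= 2."""
    periods, i, n = [], 0, len(qualifies)
    while i < n:
        if qualifies[i]:
            j = i
            while j + 1 < n and qualifies[j + 1]:
                j += 1
            if j - i + 1 >= 2:
                periods.append(
                    RiskPeriod(start + timedelta(days=i), start + timedelta(days=j))
                )
            i = j + 1
        else:
            i += 1
    return periods


class TestSmithDetector:
    def test_cold_dry_month_has_no_periods(self):
        temp, rh = hourly_series([(5.0, 0)] * 10)
        assert detect_smith_periods(temp, rh) == []

    def test_inner_qualifying_run_detected_with_correct_length(self):
        days = [(15.0, 0), (15.0, 0), (15.0, 12), (15.0, 12), (15.0, 12)]
        temp, rh = hourly_series(days)
        periods = detect_smith_periods(temp, rh)
        assert len(periods) == 1
        assert periods[0].start_day == date(2017, 6, 3)
        assert periods[0].end_day == date(2017, 6, 5)
        assert periods[0].n_days == 3

    def test_isolated_single_days_do_not_qualify(self):
        days = [(15.0, 12), (15.0, 0), (15.0, 12)]
        temp, rh = hourly_series(days)
        assert detect_smith_periods(temp, rh) == []

    def test_misaligned_series_raise(self):
        temp, rh = hourly_series([(15.0, 12)] * 3)
        with pytest.raises(AlignmentError):
            detect_smith_periods(temp.iloc[:-1], rh)

    def test_partial_day_excluded_with_warning(self):
        temp, rh = hourly_series([(15.0, 12)] * 3)
        with pytest.warns(UserWarning, match="partial day"):
            periods = detect_smith_periods(temp.iloc[:-4], rh.iloc[:-4])
        assert periods == [RiskPeriod(date(2017, 6, 1), date(2017, 6, 2))]

    def test_hour_order_within_a_day_is_irrelevant(self):
        rng = np.random.default_rng(3)
        temp = 10.0 + rng.uniform(0, 8, 24)
        rh = np.where(rng.random(24) < 0.5, 95.0, 60.0)
        perm = rng.permutation(24)
        assert smith_day_qualifies(temp, rh) == \
            smith_day_qualifies(temp[perm], rh[perm])

    @settings(max_examples=1000, deadline=None)
    @given(data=st.data())
    def test_matches_run_scan_oracle_on_random_months(self, data):
        """Detector output equals the exhaustive run-scan oracle on random
        synthetic weather months."""
        n_days = data.draw(st.integers(3, 31))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        temps = rng.uniform(6.0, 14.0, n_days)  # straddles the 10 degree gate
        wet_hours = rng.integers(0, 25, n_days)  # straddles the 11-hour gate
        temp, rh = hourly_series(list(zip(temps, wet_hours)))
        qualifies = [t >= 10.0 and w >= 11 for t, w in zip(temps, wet_hours)]
        assert detect_smith_periods(temp, rh) == \
            oracle_periods(qualifies, date(2017, 6, 1))


class TestCorrelation:
    def test_self_correlation_is_one(self):
        s = pd.Series([1.0, 2.0, 5.0, 3.0])
        assert sensor_correlation(s, s) == pytest.approx(1.0)

    def test_negation_is_minus_one(self):
        s = pd.Series([1.0, 2.0, 5.0, 3.0])
        assert sensor_correlation(s, -s) == pytest.approx(-1.0)

    def test_zero_variance_is_degenerate(self):
        s = pd.Series([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate"):
            sensor_correlation(s, pd.Series([5.0, 5.0, 5.0]))

    def test_lagged_damped_soil_tracks_ambient(self):
        """Noise-free simulated soil temperature (ambient lagged 2 h and
        damped) correlates strongly with ambient temperature."""
        from phenosync.simulate import WeatherModel, simulate_weather

        model = WeatherModel(
            noise_sd={v: 0.0 for v in (
                "ambient_temp_C", "rel_humidity_pct", "light_lux",
                "soil_temp_C", "soil_moisture_pct", "device_temp_C")},
            soil_lag_h=2,
        )
        frame = simulate_weather(model, days=5)
        # align at the lag: soil at t+lag tracks ambient at t
        r = sensor_correlation(
            frame["ambient_temp_C"], frame["soil_temp_C"].shift(-model.soil_lag_h)
        )
        assert r > 0.9
        # even unshifted, the positive association survives the phase offset
        assert sensor_correlation(
            frame["ambient_temp_C"], frame["soil_temp_C"]
        ) > 0.5
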