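import numpy as np
import pandas as pd
import pytest

import frontforage as ff
from frontforage.preprocessing import Trip, _runs
from frontforage.projection import LocalProjection

COLONY = (-2.64, 56.08)
PROJ = LocalProjection(*COLONY)


def fixes_frame(times_s, x_km, y_km, bird="b1", age="adult"):
    lon, lat = PROJ.inverse(np.asarray(x_km) * 1e3, np.asarray(y_km) * 1e3)
    return pd.DataFrame(
        {
            "bird_id": bird,
            "age_class": age,
            "timestamp": pd.Timestamp("2015-06-10")
            + pd.to_timedelta(times_s, unit="s"),
            "lon": lon,
            "lat": lat,
        }
    )


def make_trip(times_s, x_km, y_km, bird="b1", age="adult"):
    """Build a Trip fixture directly (bypasses the duration threshold)."""
    x = np.asarray(x_km, dtype=float) * 1e3
    y = np.asarray(y_km, dtype=float) * 1e3
    lon, lat = PROJ.inverse(x, y)
    df = pd.DataFrame(
        {
            "time": pd.Timestamp("2015-06-10")
            + pd.to_timedelta(times_s, unit="s"),
            "lon": lon,
            "lat": lat,
            "x": x,
            "y": y,
        }
    )
    return Trip("t0", bird, age, df)


class TestSegmentation:
    def test_all_near_colony_gives_no_trips(self):
        t = np.arange(20) * 120
        df = fixes_frame(t, np.full(20, 3.0), np.full(20, 4.0))
        assert ff.segment_trips(df, COLONY) == []

    def test_short_excursion_fails_duration_threshold(self):
        # 12 km away but only 30 min -> excluded
        t = np.arange(30) * 120
        x = np.zeros(30)
        x[5:20] = 12.0  # 15 fixes = 28 min span away
        x[20:] = 0.0
        df = fixes_frame(t, x, np.zeros(30))
        df = df.drop(index=range(6, 19)).reset_index(drop=True)  # 2 fixes away
        assert ff.segment_trips(df, COLONY) == []

    def test_single_qualifying_excursion_recovered(self):
        # 30 fixes at 2 min; one ~52-min excursion to 15 km qualifies
        t = np.arange(30) * 120
        x = np.zeros(30)
        x[2:29] = 15.0
        df = fixes_frame(t, x, np.zeros(30))
        trips = ff.segment_trips(df, COLONY)
        assert len(trips) == 1
        # the trip holds exactly the far fixes, verified by direct distance
        xx, yy = PROJ.forward(df["lon"].values, df["lat"].values)
        expect = np.flatnonzero(np.hypot(xx, yy) > 10_000)
        got_times = trips[0].fixes["time"].values
        np.testing.assert_array_equal(got_times, df["timestamp"].values[expect])

    def test_invariant_to_padding_with_colony_fixes(self):
        t = np.arange(60) * 120
        x = np.concatenate([np.zeros(5), np.full(50, 20.0), np.zeros(5)])
        df = fixes_frame(t, x, np.zeros(60))
        base = ff.segment_trips(df, COLONY)
        pad_before = fixes_frame(-120 * np.arange(1, 4)[::-1], [0, 0, 0], [0, 0, 0])
        pad_after = fixes_frame(60 * 120 + 120 * np.arange(3), [0] * 3, [0] * 3)
        padded = pd.concat([pad_before, df, pad_after], ignore_index=True)
        got = ff.segment_trips(padded, COLONY)
        assert len(got) == len(base) == 1
        np.testing.assert_array_equal(
            got[0].fixes["time"].values, base[0].fixes["time"].values
        )

    def test_runs_helper(self):
        assert list(_runs(np.array([True, True, False, True]))) == [(0, 2), (3, 4)]
        assert list(_runs(np.array([], dtype=bool))) == []


class TestRegularize:
    def test_idempotent_on_regular_trip(self):
        trip = make_trip(np.arange(25) * 120, np.linspace(12, 30, 25), np.zeros(25))
        reg = ff.regularize(trip, 120.0, colony=COLONY)
        np.testing.assert_allclose(reg.fixes["x"], trip.fixes["x"], atol=1e-9)
        assert not reg.fixes["interpolated"].any()

    def test_midpoint_inserted_for_240s_gap(self):
        trip = Trip(
            "t",
            "b",
            "adult",
            pd.DataFrame(
                {
                    "time": pd.to_datetime(["2015-06-10 00:00", "2015-06-10 00:04"]),
                    "lon": [0.0, 0.0],
                    "lat": [0.0, 0.0],
                    "x": [12_000.0, 14_000.0],
                    "y": [0.0, 1_000.0],
                }
            ),
        )
        reg = ff.regularize(trip, 120.0)
        assert len(reg) == 3
        assert reg.fixes["x"].iloc[1] == pytest.approx(13_000.0, abs=1e-6)
        assert reg.fixes["y"].iloc[1] == pytest.approx(500.0, abs=1e-6)
        assert bool(reg.fixes["interpolated"].iloc[1])

    def test_long_gap_fixes_on_chord_and_flagged(self):
        # 10-min gap: the 4 interpolated fixes are collinear on the chord
        times = np.array([0, 120, 720, 840])
        x = np.array([12.0, 13.0, 19.0, 20.0])
        y = np.array([5.0, 6.0, 12.0, 13.0])
        trip = make_trip(times, x, y)
        reg = ff.regularize(trip, 120.0, gap_flag_s=300.0, colony=COLONY)
        assert len(reg) == 8
        mid = reg.fixes.iloc[2:6]
        assert mid["in_long_gap"].all()
        # collinearity: cross product of chord with each inserted point = 0
        p0 = np.array([13_000.0, 6_000.0])
        p1 = np.array([19_000.0, 12_000.0])
        v = p1 - p0
        for _, row in mid.iterrows():
            w = np.array([row.x, row.y]) - p0
            assert abs(v[0] * w[1] - v[1] * w[0]) < 1e-6

    def test_single_fix_trip_errors(self):
        trip = Trip(
            "t", "b", "adult",
            pd.DataFrame(
                {"time": [pd.Timestamp("2015-06-10")], "lon": [0.0], "lat": [0.0],
                 "x": [0.0], "y": [0.0]}
            ),
        )
        with pytest.raises(ValueError):
            ff.regularize(trip)


class TestStepsAndTurns:
    def test_collinear_gives_zero_turns(self):
        trip = make_trip(np.arange(25) * 120, np.linspace(12, 36, 25), np.zeros(25))
        s = ff.steps_and_turns(ff.regularize(trip, colony=COLONY))
        assert np.isnan(s.turns[0])
        np.testing.assert_allclose(s.turns[1:], 0.0, atol=1e-9)
        np.testing.assert_allclose(s.steps, 1.0, atol=1e-9)

    def test_right_angle_dogleg_sign(self):
        # east then north = left turn = +pi/2 under the signed convention
        trip = make_trip(
            np.arange(3) * 120, [12.0, 13.0, 13.0], [0.0, 0.0, 1.0]
        )
        s = ff.steps_and_turns(ff.regularize(trip, colony=COLONY))
        assert abs(s.turns[1] - (-np.pi / 2)) < 1e-9 or abs(
            s.turns[1] - np.pi / 2
        ) < 1e-9
        # east->north is a turn toward the left (counter-clockwise): negative
        # under heading = atan2(dx, dy) convention
        assert s.turns[1] == pytest.approx(-np.pi / 2)

    def test_matches_independent_atan2_recomputation(self):
        rng = np.random.default_rng(0)
        n = 40
        x = 12.0 + np.cumsum(rng.normal(0.5, 0.3, n))
        y = np.cumsum(rng.normal(0.2, 0.4, n))
        trip = make_trip(np.arange(n) * 120, x, y)
        reg = ff.regularize(trip, colony=COLONY)
        s = ff.steps_and_turns(reg)
        xs = reg.fixes["x"].values / 1000
        ys = reg.fixes["y"].values / 1000
        head = np.arctan2(np.diff(xs), np.diff(ys))
        dturn = np.diff(head)
        dturn = np.arctan2(np.sin(dturn), np.cos(dturn))
        np.testing.assert_allclose(s.turns[1:], dturn, atol=1e-9)

    def test_zero_length_step_marks_adjacent_turns_undefined(self):
        trip = make_trip(
            np.arange(5) * 120, [12.0, 13.0, 13.0, 13.0, 14.0], [0.0] * 5
        )
        s = ff.steps_and_turns(ff.regularize(trip, colony=COLONY))
        assert s.steps[1] == 0.0 or s.steps[2] == 0.0
        zero = np.flatnonzero(s.steps == 0.0)
        for z in zero:
            assert np.isnan(s.turns[z])
            if z + 1 < len(s.turns):
                assert np.isnan(s.turns[z + 1])


class TestTripMetrics:
    def test_out_and_back(self):
        # straight out 100 km east and back at constant speed
        n = 101
        x = np.concatenate([np.linspace(0, 100, n), np.linspace(100, 0, n)[1:]])
        t = np.arange(len(x)) * 120
        df = fixes_frame(t, x, np.zeros_like(x))
        trips = ff.segment_trips(df, COLONY)
        m = ff.trip_metrics(ff.regularize(trips[0], colony=COLONY), COLONY)
        # fixes inside 10 km are excluded, so the polyline spans 11..100..11
        assert m.length_km == pytest.approx(2 * (100 - 11), rel=0.02)
        assert m.range_km == pytest.approx(100.0, abs=0.1)
        assert m.terminal_x == pytest.approx(100_000.0, abs=50.0)

    def test_departure_angle_of_identical_bearings(self):
        # all early bearings equal -> circular mean equals that bearing
        ang = 0.3
        r = np.linspace(11, 40, 30)
        x = r * np.sin(ang)
        y = r * np.cos(ang)
        trip = make_trip(np.arange(30) * 120, x, y)
        m = ff.trip_metrics(ff.regularize(trip, colony=COLONY), COLONY)
        assert m.departure_angle == pytest.approx(ang, abs=1e-6)
        assert m.n_departure_bearings == 5

    def test_unit_square_mcp_area(self):
        x = np.array([20.0, 21.0, 21.0, 20.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        trip = make_trip(np.arange(4) * 120, x, y)
        m = ff.trip_metrics(trip, COLONY)
        assert m.area_km2 == pytest.approx(1.0, rel=1e-6)

    def test_fewer_than_five_bearings_flagged(self):
        trip = make_trip(np.arange(22) * 120,
                         [0, 5, 11, 12] + [0] * 18, [0.0] * 22)
        m = ff.trip_metrics(trip, COLONY)
        assert m.n_departure_bearings == 2


class TestCovariate:
    def test_constant_field_gives_constant_abs_covariate(self, small_cohort):
        s = small_cohort["series"][0]
        fld = small_cohort["cohort"].fsle.copy()
        fld.values[:] = -0.37
        out = ff.attach_covariate(s, fld, small_cohort["cfg"].colony)
        np.testing.assert_allclose(out.covariate, 0.37)

    def test_gradient_field_matches_direct_lookup(self, small_cohort):
        cfg = small_cohort["cfg"]
        fld = small_cohort["cohort"].fsle.copy()
        # deterministic gradient in the lon direction
        fld.values[:] = -np.abs(fld["lon"].values)[None, None, :]
        s = small_cohort["series"][0]
        out = ff.attach_covariate(s, fld, cfg.colony)
        proj = LocalProjection(*cfg.colony)
        lon, lat = proj.inverse(s.x, s.y)
        lons = fld["lon"].values
        expect = np.abs(lons[np.argmin(np.abs(lons[None, :] - lon[:, None]), axis=1)])
        np.testing.assert_allclose(out.covariate, expect, atol=1e-12)


def test_total_step_length_bounded_by_raw_polyline(small_cohort):
    """Interpolation onto the lattice cannot lengthen the path."""
    cfg = small_cohort["cfg"]
    from conftest import cohort_to_fixes

    fixes = cohort_to_fixes(small_cohort["cohort"])
    raw_trips = ff.segment_trips(fixes, cfg.colony)
    for tr in raw_trips[:10]:
        raw_len = np.hypot(
            np.diff(tr.fixes["x"]), np.diff(tr.fixes["y"])
        ).sum()
        reg = ff.regularize(tr, colony=cfg.colony)
        reg_len = np.hypot(np.diff(reg.fixes["x"]), np.diff(reg.fixes["y"])).sum()
        assert reg_len <= raw_len + 1e-6
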