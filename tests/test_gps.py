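import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import birdyear as by
from birdyear.gps import EARTH_RADIUS_KM, great_circle_km


def _fix_frame(times, lats, lons, bird="b1"):
    return pd.DataFrame(
        {"bird_id": bird, "time": pd.to_datetime(times, utc=True), "lat": lats, "lon": lons}
    )


class TestGreatCircle:
    def test_zero_for_identical_points(self):
        assert great_circle_km(-39.25, 146.5, -39.25, 146.5) == 0.0

    def test_one_degree_meridian_arc(self):
        # meridian arc = R * dphi = 6371.0088 * pi/180 = 111.195 km
        assert great_circle_km(-39.25, 146.5, -38.25, 146.5) == pytest.approx(
            111.19, abs=0.01
        )

    def test_matches_spherical_law_of_cosines(self, rng):
        lat1, lat2 = rng.uniform(-80, 80, (2, 100))
        lon1, lon2 = rng.uniform(-179, 179, (2, 100))
        d = great_circle_km(lat1, lon1, lat2, lon2)
        p1, p2 = np.radians(lat1), np.radians(lat2)
        dl = np.radians(lon2 - lon1)
        oracle = EARTH_RADIUS_KM * np.arccos(
            np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
        )
        assert np.all(np.abs(d - oracle) < 1e-3)  # within 1 m

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            great_circle_km(95.0, 0.0, 0.0, 0.0)


class TestSpeedFilter:
    def test_keeps_sub_threshold_pair(self):
        # 1 km in 1 min = 16.7 m/s, below the 20 m/s threshold
        df = _fix_frame(
            ["2019-01-01T00:00", "2019-01-01T00:01"], [-39.0, -39.0 + 1 / 111.195], [146.5, 146.5]
        )
        assert len(by.speed_filter(df)) == 2

    def test_removes_spike_keeps_neighbours(self):
        # middle fix implies ~111 km in 10 min (185 m/s)
        df = _fix_frame(
            ["2019-01-01T00:00", "2019-01-01T00:10", "2019-01-01T00:20"],
            [-39.0, -38.0, -39.0],
            [146.5, 146.5, 146.5],
        )
        out = by.speed_filter(df)
        assert list(out["lat"]) == [-39.0, -39.0]

    def test_removes_exactly_injected_spikes(self, sim_track, rng):
        cfg, fixes, _ = sim_track
        df = fixes.copy()
        spike_rows = rng.choice(np.arange(10, len(df) - 10), 5, replace=False)
        df.loc[spike_rows, "lat"] += 1.5  # ~170 km displacement in 10 min
        out = by.speed_filter(df)
        # brute-force pairwise speed audit of the output
        t = pd.to_datetime(out["time"]).astype("int64").to_numpy() / 1e9
        d = great_circle_km(
            out["lat"][:-1].to_numpy(), out["lon"][:-1].to_numpy(),
            out["lat"][1:].to_numpy(), out["lon"][1:].to_numpy(),
        )
        assert np.all(d * 1000 / np.diff(t) <= 20.0)
        assert len(out) == len(df) - 5
        assert not set(df.loc[spike_rows, "time"]) & set(out["time"])

    def test_idempotent(self, sim_track):
        _, fixes, _ = sim_track
        once = by.speed_filter(fixes)
        twice = by.speed_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input(self):
        out = by.speed_filter(_fix_frame([], [], []))
        assert len(out) == 0


class TestRegularize:
    def test_on_grid_is_identity(self):
        times = pd.date_range("2019-01-01", periods=5, freq="10min", tz="UTC")
        df = _fix_frame(times, np.linspace(-39, -38.9, 5), np.full(5, 146.5))
        out = by.regularize(df, 10)
        assert np.allclose(out["lat"], df["lat"])
        assert not out["interpolated"].any()

    def test_midpoint_inserted(self):
        df = _fix_frame(
            ["2019-01-01T00:00", "2019-01-01T00:20"], [-39.0, -38.8], [146.0, 146.4]
        )
        out = by.regularize(df, 10)
        assert len(out) == 3
        assert out.loc[1, "lat"] == pytest.approx(-38.9)
        assert out.loc[1, "lon"] == pytest.approx(146.2)
        assert bool(out.loc[1, "interpolated"])

    def test_long_gap_emitted_missing(self):
        times = ["2019-01-01T00:00", "2019-01-01T00:10", "2019-01-01T02:00"]
        df = _fix_frame(times, [-39.0, -39.0, -38.5], [146.0, 146.0, 146.0])
        out = by.regularize(df, 10, max_gap=4)
        inside = out[(out["time"] > times[1]) & (out["time"] < times[2])]
        assert inside["lat"].isna().all()

    def test_thinned_track_rms_error_below_step_length(self, sim_track):
        cfg, fixes, _ = sim_track
        thinned = fixes.iloc[::2].reset_index(drop=True)
        out = by.regularize(thinned, cfg.gps_interval_min)
        merged = out.merge(fixes, on="time", suffixes=("_est", "_true"))
        err_km = great_circle_km(
            merged["lat_est"].to_numpy(), merged["lon_est"].to_numpy(),
            merged["lat_true"].to_numpy(), merged["lon_true"].to_numpy(),
        )
        max_step_km = 20.0 * cfg.gps_interval_min * 60 / 1000  # vmax * interval
        assert np.sqrt(np.mean(err_km**2)) < max_step_km

    def test_single_fix_warns(self):
        df = _fix_frame(["2019-01-01T00:00"], [-39.0], [146.0])
        with pytest.warns(UserWarning):
            out = by.regularize(df, 10)
        assert len(out) == 1


class TestTrips:
    colony = (-39.25, 146.5)

    def test_all_at_colony_no_trips(self):
        times = pd.date_range("2019-01-01", periods=10, freq="10min", tz="UTC")
        df = _fix_frame(times, np.full(10, -39.25), np.full(10, 146.5))
        assert by.segment_trips(df, self.colony) == []

    def test_single_out_and_back(self):
        times = pd.date_range("2019-01-01", periods=7, freq="1h", tz="UTC")
        lats = [-39.25, -39.5, -40.0, -40.25, -40.0, -39.5, -39.25]
        df = _fix_frame(times, lats, np.full(7, 146.5))
        trips = by.segment_trips(df, self.colony)
        assert len(trips) == 1
        assert trips[0].complete
        assert trips[0].start == times[1] and trips[0].end == times[5]

    def test_boundaries_match_simulator_truth(self, sim_track):
        cfg, fixes, truth = sim_track
        reg = by.regularize(by.speed_filter(fixes), cfg.gps_interval_min)
        trips = by.segment_trips(reg, cfg.colony, cfg.colony_radius_km)
        from birdyear.synthetic import completed_trips

        complete = [t for t in trips if t.complete]
        truth_complete = completed_trips(truth)
        assert len(complete) == len(truth_complete)
        tol = pd.Timedelta(minutes=cfg.gps_interval_min)
        for trip, (t0, t1) in zip(complete, truth_complete):
            assert abs(trip.start - t0) <= tol
            assert abs(trip.end - t1) <= tol

    def test_out_and_back_meridian_metrics(self):
        times = pd.date_range("2019-01-01", periods=5, freq="3h", tz="UTC")
        lats = [-39.25, -39.75, -40.25, -39.75, -39.25]
        df = _fix_frame(times, lats, np.full(5, 146.5))
        trips = by.segment_trips(df, self.colony)
        t = by.trip_metrics(trips[0], self.colony)
        assert t.total_distance_km == pytest.approx(2.0 * 111.195, rel=0.01)
        assert t.max_range_km == pytest.approx(111.195, rel=0.01)

    def test_stationary_trip(self):
        times = pd.date_range("2019-01-01", periods=4, freq="1h", tz="UTC")
        df = _fix_frame(times, np.full(4, -40.25), np.full(4, 146.5))
        trips = by.segment_trips(df, self.colony)
        t = by.trip_metrics(trips[0], self.colony)
        assert t.total_distance_km == pytest.approx(0.0, abs=1e-9)
        assert t.max_range_km == pytest.approx(111.195, rel=0.01)

    @pytest.mark.parametrize(
        "duration_h,expected", [(27.0, "short"), (89.0, "long"), (48.0, "short")]
    )
    def test_trip_class_threshold(self, duration_h, expected):
        t = by.Trip(
            bird_id="b", start=pd.Timestamp("2019-01-01", tz="UTC"),
            end=pd.Timestamp("2019-01-01", tz="UTC") + pd.Timedelta(hours=duration_h),
            fixes=pd.DataFrame(), complete=True, stage="chick_rearing",
            duration_h=duration_h,
        )
        assert by.classify_trip(t) == expected

    def test_incubation_trip_class_none(self):
        t = by.Trip(
            bird_id="b", start=pd.Timestamp("2019-01-01", tz="UTC"),
            end=pd.Timestamp("2019-01-02", tz="UTC"), fixes=pd.DataFrame(),
            complete=True, stage="incubation", duration_h=24.0,
        )
        assert by.classify_trip(t) == "none"


class TestTripInvariants:
    def test_total_distance_bounds_max_range(self, breeding_bundle):
        for t in breeding_bundle["trips"]:
            if t.complete and len(t.fixes) >= 2:
                assert t.total_distance_km >= t.max_range_km - 1e-9

    def test_trips_partition_off_colony_time(self, breeding_bundle):
        trips = breeding_bundle["trips"]
        for a, b in zip(trips[:-1], trips[1:]):
            assert a.end < b.start

    def test_duration_correlates_with_range(self, breeding_bundle):
        tab = breeding_bundle["trip_table"]
        tab = tab[tab["complete"]]
        rho, _ = spearmanr(tab["duration_h"], tab["max_range_km"])
        assert rho > 0
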