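import numpy as np
import pandas as pd
import pytest

import birdyear as by
from birdyear import phenology
from birdyear.phenology import AttendanceEvent


def _activity(start, hours, wet_value=1):
    idx = pd.date_range(start, periods=int(hours * 120), freq="30s", tz="UTC")
    wet = np.full(len(idx), wet_value)
    return pd.DataFrame({"time": idx, "wet": wet})


def _daily(dates, fracs):
    return pd.Series(fracs, index=pd.DatetimeIndex(dates, tz="UTC"), name="wet_fraction")


class TestBlockActivity:
    def test_all_wet_day(self):
        blocks, daily = by.block_activity(_activity("2020-03-01", 24, 1))
        assert daily.iloc[0] == 1.0
        assert len(blocks) == 6

    def test_one_wet_block_of_six(self):
        act = _activity("2020-03-01", 24, 0)
        t = pd.to_datetime(act["time"])
        first_block = t < pd.Timestamp("2020-03-01T04:00Z")
        act.loc[first_block.to_numpy(), "wet"] = 1
        _, daily = by.block_activity(act)
        assert daily.iloc[0] == pytest.approx(1 / 6)

    def test_block_sample_count(self):
        blocks, _ = by.block_activity(_activity("2020-03-01", 4, 1))
        assert blocks["n_samples"].iloc[0] == 480


class TestMoultWindow:
    def test_clean_twenty_day_window(self):
        dates = pd.date_range("2020-02-01", periods=40, freq="D")
        fracs = [0.5] * 10 + [0.95] * 20 + [0.5] * 10
        w = by.detect_moult_window(_daily(dates, fracs))
        assert w[0] == dates[10].tz_localize("UTC")
        assert w[1] == dates[29].tz_localize("UTC")

    def test_no_window_when_never_wet_enough(self):
        dates = pd.date_range("2020-02-01", periods=30, freq="D")
        assert by.detect_moult_window(_daily(dates, [0.5] * 30)) is None

    def test_short_run_below_min_days(self):
        dates = pd.date_range("2020-02-01", periods=10, freq="D")
        fracs = [0.5] * 4 + [0.95] * 3 + [0.5] * 3
        assert by.detect_moult_window(_daily(dates, fracs)) is None

    def test_tolerates_small_gaps(self):
        dates = pd.date_range("2020-02-01", periods=30, freq="D")
        fracs = [0.95] * 10 + [0.7] * 2 + [0.95] * 10 + [0.5] * 8
        w = by.detect_moult_window(_daily(dates, fracs))
        assert (w[1] - w[0]).days + 1 == 22

    def test_noisy_thirty_day_truth_overlap(self, rng):
        # 10% of the 2880 daily immersion samples are misread at random, so
        # the observed fraction is a binomial draw around 0.9*p + 0.05
        dates = pd.date_range("2020-02-01", periods=80, freq="D")
        truth = (dates >= "2020-02-20") & (dates <= "2020-03-20")  # 30 days
        base = np.where(truth, 0.97, 0.6)
        p_obs = 0.9 * base + 0.1 * 0.5
        noisy = rng.binomial(2880, p_obs) / 2880.0
        w = by.detect_moult_window(_daily(dates, noisy))
        assert w is not None
        found = pd.date_range(w[0].tz_localize(None), w[1].tz_localize(None), freq="D")
        overlap = len(set(found) & set(dates[truth]))
        assert overlap / truth.sum() >= 0.8


def _positions_at(dist_km_east, times, colony=(-39.25, 146.5)):
    lon = colony[1] + np.asarray(dist_km_east) / (111.195 * np.cos(np.radians(colony[0])))
    return pd.DataFrame(
        {"time": pd.to_datetime(times, utc=True), "kind": "noon", "lat": colony[0],
         "lon": lon, "equinox_masked": False}
    )


class TestAttendance:
    colony = (-39.25, 146.5)

    def test_continuously_wet_no_events(self):
        blocks, _ = by.block_activity(_activity("2020-05-01", 72, 1))
        pos = _positions_at([50] * 3, ["2020-05-01", "2020-05-02", "2020-05-03"])
        assert by.detect_attendance(blocks, pos, self.colony) == []

    def test_nine_hour_dry_run_within_range(self):
        act = _activity("2020-05-01", 48, 1)
        t = pd.to_datetime(act["time"])
        dry = (t >= "2020-05-01T11:30Z") & (t < "2020-05-01T20:30Z")  # 9 h
        act.loc[dry.to_numpy(), "wet"] = 0
        blocks, _ = by.block_activity(act)
        pos = _positions_at([150, 150], ["2020-05-01T02:00", "2020-05-02T02:00"])
        events = by.detect_attendance(blocks, pos, self.colony)
        assert len(events) == 1
        assert events[0].evidence == "dry_run"

    def test_distant_dry_run_rejected(self):
        act = _activity("2020-05-01", 48, 1)
        t = pd.to_datetime(act["time"])
        dry = (t >= "2020-05-01T08:00Z") & (t < "2020-05-01T20:00Z")
        act.loc[dry.to_numpy(), "wet"] = 0
        blocks, _ = by.block_activity(act)
        pos = _positions_at([1500, 1500], ["2020-05-01T02:00", "2020-05-02T02:00"])
        assert by.detect_attendance(blocks, pos, self.colony) == []

    def test_simulated_nights_recovered_exactly(self, gls_year, nonbreeding_bundle):
        _, truth, _, _ = gls_year
        events = nonbreeding_bundle["attendance"]
        assert len(events) == len(truth.attendance_events)
        for ev, (a, b) in zip(events, truth.attendance_events):
            assert abs(ev.start.normalize() - a.normalize()) <= pd.Timedelta(days=1)

    def test_events_never_overlap(self, nonbreeding_bundle):
        events = nonbreeding_bundle["attendance"]
        for a, b in zip(events[:-1], events[1:]):
            assert a.end < b.start


class TestBoundaries:
    def _ev(self, start, end):
        return AttendanceEvent(
            start=pd.Timestamp(start, tz="UTC"), end=pd.Timestamp(end, tz="UTC"),
            evidence="dry_run",
        )

    def test_simple_gap(self):
        events = [self._ev("2019-01-31T18:00", "2019-02-01T06:00"),
                  self._ev("2019-06-05T10:00", "2019-06-05T20:00")]
        dep, ret = by.breeding_boundaries(events)
        assert dep == pd.Timestamp("2019-02-01", tz="UTC")
        assert ret == pd.Timestamp("2019-06-05", tz="UTC")

    def test_no_gap_raises(self):
        events = [
            self._ev(f"2019-{m:02d}-{d:02d}T10:00", f"2019-{m:02d}-{d:02d}T20:00")
            for m in range(1, 13)
            for d in (1, 8, 15, 22)
        ]
        with pytest.raises(ValueError, match="no migration gap"):
            by.breeding_boundaries(events)

    def test_simulated_boundaries_within_one_day(self, gls_year, nonbreeding_bundle):
        _, truth, _, _ = gls_year
        dep, ret = nonbreeding_bundle["boundaries"]
        assert abs(dep - truth.last_attendance) <= pd.Timedelta(days=1)
        assert abs(ret - truth.first_return) <= pd.Timedelta(days=1)


class TestMigration:
    colony = (-39.25, 146.5)

    def test_duration_date_arithmetic(self):
        pos = _positions_at([100, 2000, 100], ["2019-02-15", "2019-04-01", "2019-06-01"])
        b = (pd.Timestamp("2019-02-01", tz="UTC"), pd.Timestamp("2019-06-05", tz="UTC"))
        m = by.migration_summary(pos, b, self.colony)
        assert m.duration_d == 124.0

    def test_stationary_bird_near_zero_range(self):
        times = pd.date_range("2019-02-02", periods=20, freq="D", tz="UTC")
        pos = _positions_at([0.3] * 20, times)
        b = (times[0], times[-1])
        m = by.migration_summary(pos, b, self.colony)
        assert m.max_range_km < 5.0

    def test_out_and_back_range_under_noise(self, rng):
        # 2000 km out-and-back; positions blurred with per-axis 116-km noise
        # (mean radial error ~186 km, the typical geolocation accuracy)
        days = pd.date_range("2019-02-02", periods=120, freq="D", tz="UTC")
        leg = np.concatenate(
            [np.linspace(0, 2000, 30), np.full(60, 2000), np.linspace(2000, 0, 30)]
        )
        sd_lat = 116 / 111.195
        sd_lon = 116 / (111.195 * np.cos(np.radians(39.25)))
        pos = _positions_at(leg, days)
        pos["lat"] += rng.normal(0, sd_lat, len(pos))
        pos["lon"] += rng.normal(0, sd_lon, len(pos))
        m = by.migration_summary(pos, (days[0], days[-1]), self.colony)
        # oracle: Monte-Carlo distribution of the max range under the same
        # noise model applied to the true path
        oracle = []
        for _ in range(200):
            p = _positions_at(leg, days)
            p["lat"] += rng.normal(0, sd_lat, len(p))
            p["lon"] += rng.normal(0, sd_lon, len(p))
            oracle.append(by.migration_summary(p, (days[0], days[-1]), self.colony).max_range_km)
        lo, hi = np.quantile(oracle, [0.005, 0.995])
        assert m.max_range_km >= 2000 - 200  # never underestimates materially
        assert lo <= m.max_range_km <= hi

    def test_duration_invariant_to_position_noise(self, gls_year, nonbreeding_bundle):
        _, truth, _, _ = gls_year
        m = nonbreeding_bundle["migration"]
        expected = float((truth.first_return - truth.last_attendance).days)
        assert m.duration_d == pytest.approx(expected, abs=1)

    def test_noisy_total_distance_exceeds_true_path(self, gls_year, nonbreeding_bundle):
        _, truth, _, _ = gls_year
        dp = truth.daily_positions
        t = pd.to_datetime(dp["date"])
        dep, ret = nonbreeding_bundle["boundaries"]
        span = dp[(t >= dep) & (t <= ret)]
        lat, lon = span["lat"].to_numpy(), span["lon"].to_numpy()
        true_total = np.sum(
            by.great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        )
        assert nonbreeding_bundle["migration"].total_distance_km >= true_total
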