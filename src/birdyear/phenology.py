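"""Phenology from immersion (wet/dry), light and position streams.

A leg-mounted conductivity switch sampled every 30 s records whether the
logger is in seawater.  Summarized into 4-hour blocks and daily wet
fractions, the record carries rich phenological signal:

* **flight-feather moult** depresses flight: a run of days with wet
  fraction > 90% marks the moult window;
* **burrow attendance**: a prolonged all-dry run (> 8 h) while the bird is
  within ~200 km of the colony — or continuous darkness during expected
  daylight (bird underground) — marks a night in the burrow;
* **breeding boundaries and migration**: the last attendance before the
  long at-sea gap and the first attendance after it bound the post-breeding
  migration, whose duration, total distance travelled and maximum range are
  then read from the geolocation positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .gps import great_circle_km

BLOCK_HOURS = 4


def block_activity(activity: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Summarize 30-s wet/dry samples into 4-h blocks and daily wet fractions.

    ``activity`` has columns ``time`` (UTC) and ``wet`` (0/1).  Blocks are
    aligned to 00:00 UTC (6 per day); the daily fraction is the
    sample-weighted mean over the day's blocks.  Days with no samples are
    absent from the daily series.

    Returns ``(blocks, daily)``: blocks frame with ``block_start, wet_fraction,
    n_samples`` and a daily Series indexed by date.
    """
    df = activity.dropna(subset=["wet"]).copy()
    t = pd.to_datetime(df["time"])
    if t.dt.tz is None:
        t = t.dt.tz_localize("UTC")
    df["block_start"] = t.dt.floor(f"{BLOCK_HOURS}h")
    grouped = df.groupby("block_start")["wet"]
    blocks = pd.DataFrame(
        {"wet_fraction": grouped.mean(), "n_samples": grouped.size()}
    ).reset_index()
    day = blocks["block_start"].dt.normalize()
    wet_samples = blocks["wet_fraction"] * blocks["n_samples"]
    daily = wet_samples.groupby(day).sum() / blocks["n_samples"].groupby(day).sum()
    daily.index.name = "date"
    daily.name = "wet_fraction"
    return blocks, daily


def detect_moult_window(
    daily: pd.Series,
    wet_threshold: float = 0.9,
    gap_days: int = 2,
    min_days: int = 5,
) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Longest run of days with wet fraction above ``wet_threshold``.

    Up to ``gap_days`` consecutive sub-threshold days are tolerated inside a
    run (observation noise); the window's endpoints are always
    above-threshold days.  Returns ``(first_day, last_day)`` or ``None`` if
    the longest run is shorter than ``min_days``.
    """
    s = daily.dropna().sort_index()
    if len(s) == 0:
        return None
    dates = pd.DatetimeIndex(s.index)
    above = (s.to_numpy(float) > wet_threshold)
    best: tuple[pd.Timestamp, pd.Timestamp] | None = None
    best_len = 0
    start = None
    gap = 0
    last_above = None
    for i in range(len(dates)):
        # calendar gaps in the record break runs like sub-threshold days
        if i > 0:
            missing = int((dates[i] - dates[i - 1]).days) - 1
            gap += missing
        if above[i]:
            if start is None or gap > gap_days:
                start = dates[i]
            gap = 0
            last_above = dates[i]
            run_len = int((last_above - start).days) + 1
            if run_len > best_len:
                best_len = run_len
                best = (start, last_above)
        else:
            gap += 1
    if best is None or best_len < min_days:
        return None
    return best


@dataclass
class AttendanceEvent:
    """One burrow-attendance event (typically one night, up to a few days)."""

    start: pd.Timestamp
    end: pd.Timestamp
    evidence: str  # "dry_run" | "darkness" | "both"

    @property
    def nights(self) -> int:
        return max(1, int((self.end.normalize() - self.start.normalize()).days))


def _dry_runs(blocks: pd.DataFrame, min_dry_h: float) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Maximal runs of contiguous 100%-dry blocks spanning ≥ ``min_dry_h``.

    Block quantization truncates the true dry span: a run of fully dry 4-h
    blocks lasting exactly ``min_dry_h`` implies a true dry period *longer*
    than that (the flanking blocks are partly dry), so the comparison is
    inclusive on the block run.
    """
    b = blocks.sort_values("block_start").reset_index(drop=True)
    runs = []
    start = None
    prev_end = None
    block_td = pd.Timedelta(hours=BLOCK_HOURS)
    for _, row in b.iterrows():
        t0 = row["block_start"]
        dry = row["wet_fraction"] == 0.0 and row["n_samples"] > 0
        contiguous = prev_end is not None and t0 == prev_end
        if dry:
            if start is None or not contiguous:
                if start is not None:
                    runs.append((start, prev_end))
                start = t0
            prev_end = t0 + block_td
        else:
            if start is not None:
                runs.append((start, prev_end))
                start = None
            prev_end = t0 + block_td
    if start is not None:
        runs.append((start, prev_end))
    min_td = pd.Timedelta(hours=min_dry_h)
    return [(a, b_) for a, b_ in runs if (b_ - a) >= min_td]


def _dark_days(
    light: pd.DataFrame, colony: tuple[float, float], light_threshold: float
) -> list[pd.Timestamp]:
    """Days whose expected-daylight light never rises above threshold.

    A bird underground in its burrow records darkness during the daytime;
    expected daylight is computed from the solar elevation at the colony.
    """
    df = light.dropna(subset=["light"]).copy()
    t = pd.to_datetime(df["time"])
    if t.dt.tz is None:
        t = t.dt.tz_localize("UTC")
    elev = solar.solar_elevation(t, colony[0], colony[1])
    df["date"] = t.dt.normalize()
    df["daylight"] = elev > 0.0
    out = []
    for date, g in df.groupby("date"):
        day = g[g["daylight"]]
        if len(day) >= 12 and (day["light"] < light_threshold).all():
            out.append(date)
    return out


def detect_attendance(
    blocks: pd.DataFrame,
    positions: pd.DataFrame,
    colony: tuple[float, float],
    light: pd.DataFrame | None = None,
    light_threshold: float | None = None,
    max_dist_km: float = 200.0,
    min_dry_h: float = 8.0,
    position_window_d: float = 2.0,
) -> list[AttendanceEvent]:
    """Burrow-attendance events from dry runs, positions and (optionally) light.

    An event requires proximity — the nearest non-masked position within
    ``position_window_d`` days must lie within ``max_dist_km`` of the colony
    — combined with either a 100%-dry run longer than ``min_dry_h`` or
    continuous darkness through an expected daylight period.  Overlapping or
    abutting evidence is merged into a single event.  Candidates with no
    usable position nearby are dropped.
    """
    pos = positions.copy()
    pos = pos[pos["lat"].notna() & ~pos.get("equinox_masked", False)]
    pos_t = pd.to_datetime(pos["time"]) if len(pos) else pd.Series(dtype="datetime64[ns, UTC]")
    candidates: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    for a, b in _dry_runs(blocks, min_dry_h):
        candidates.append((a, b, "dry_run"))
    if light is not None and light_threshold is not None:
        for date in _dark_days(light, colony, light_threshold):
            candidates.append((date, date + pd.Timedelta(days=1), "darkness"))

    kept: list[tuple[pd.Timestamp, pd.Timestamp, str]] = []
    for a, b, ev in candidates:
        if len(pos) == 0:
            continue
        mid = a + (b - a) / 2
        dt_d = (pos_t - mid).dt.total_seconds().abs() / 86400.0
        near = dt_d <= position_window_d
        if not near.any():
            continue
        k = dt_d[near].idxmin()
        d = great_circle_km(pos.loc[k, "lat"], pos.loc[k, "lon"], colony[0], colony[1])
        if d <= max_dist_km:
            kept.append((a, b, ev))

    kept.sort(key=lambda x: x[0])
    events: list[AttendanceEvent] = []
    for a, b, ev in kept:
        if events and a <= events[-1].end:
            last = events[-1]
            last.end = max(last.end, b)
            if last.evidence != ev:
                last.evidence = "both"
        else:
            events.append(AttendanceEvent(start=a, end=b, evidence=ev))
    return events


def breeding_boundaries(
    events: list[AttendanceEvent], min_gap_days: float = 30.0
) -> tuple[pd.Timestamp, pd.Timestamp | None]:
    """Last burrow attendance before migration and first attendance after.

    The migration is the largest gap between consecutive attendance events;
    it must exceed ``min_gap_days``.  Dates are whole UTC days.  With events
    only before the gap (bird never detected back), first return is None.
    """
    if not events:
        raise ValueError("no attendance events")
    ev = sorted(events, key=lambda e: e.start)
    if len(ev) == 1:
        return ev[0].end.normalize(), None
    gaps = [
        (ev[i + 1].start - ev[i].end).total_seconds() / 86400.0
        for i in range(len(ev) - 1)
    ]
    k = int(np.argmax(gaps))
    if gaps[k] < min_gap_days:
        raise ValueError(
            f"no migration gap found: largest attendance gap is {gaps[k]:.1f} d "
            f"< {min_gap_days} d"
        )
    return ev[k].end.normalize(), ev[k + 1].start.normalize()


@dataclass
class MigrationSummary:
    """Post-breeding migration metrics between the attendance boundaries."""

    departure: pd.Timestamp
    first_return: pd.Timestamp | None
    duration_d: float
    total_distance_km: float
    max_range_km: float


def migration_summary(
    positions: pd.DataFrame,
    boundaries: tuple[pd.Timestamp, pd.Timestamp | None],
    colony: tuple[float, float],
) -> MigrationSummary:
    """Duration, total distance and maximum range of the migration.

    Duration is whole days between last attendance and first return.
    Distances use the retained (non-equinox-masked, latitude-bearing)
    positions between the boundaries: total distance is the sum of
    great-circle legs between successive positions; maximum range the
    largest distance to the colony.  Position noise inflates the total
    distance relative to the true path — an inherent property of summed
    noisy legs.
    """
    dep, ret = boundaries
    duration = np.nan if ret is None else float((ret - dep).days)
    pos = positions.copy()
    pos = pos[pos["lat"].notna() & ~pos.get("equinox_masked", False)]
    t = pd.to_datetime(pos["time"])
    in_span = t >= dep
    if ret is not None:
        in_span &= t <= ret
    pos = pos[in_span].sort_values("time")
    if len(pos) < 2:
        return MigrationSummary(dep, ret, duration, np.nan, np.nan)
    lat = pos["lat"].to_numpy(float)
    lon = pos["lon"].to_numpy(float)
    total = float(np.sum(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    rng = float(np.max(great_circle_km(lat, lon, colony[0], colony[1])))
    return MigrationSummary(dep, ret, duration, total, rng)
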