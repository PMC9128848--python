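"""GPS track cleaning, regularization and foraging-trip segmentation.

A central-place forager leaves its colony, travels at sea and returns; each
maximal run of fixes outside a small radius around the colony is one foraging
trip.  This module takes raw fix tables (``bird_id, time, lat, lon``), removes
speed-implausible positions, interpolates onto a regular time grid, cuts the
track into trips and computes the standard trip metrics: duration (h), total
horizontal distance travelled (km) and maximum distance from the colony (km).

Fix tables are plain :class:`pandas.DataFrame` objects with UTC timestamps;
trips are :class:`Trip` dataclasses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mean Earth radius, km (IUGG).
EARTH_RADIUS_KM = 6371.0088

#: Chick-rearing trips at most this long are "short" trips (dual foraging).
SHORT_TRIP_MAX_H = 48.0

FIX_COLUMNS = ["bird_id", "time", "lat", "lon"]


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    ok_lat = np.isnan(lat) | ((lat >= -90.0) & (lat <= 90.0))
    ok_lon = np.isnan(lon) | ((lon > -180.0) & (lon <= 180.0))
    if not ok_lat.all():
        bad = lat[~ok_lat].flat[0]
        raise ValueError(f"latitude out of range [-90, 90]: {bad}")
    if not ok_lon.all():
        bad = lon[~ok_lon].flat[0]
        raise ValueError(f"longitude out of range (-180, 180]: {bad}")


def great_circle_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km (haversine on a sphere of R=6371.0088 km).

    Accepts scalars or broadcastable arrays of signed decimal degrees.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.isscalar(lat1) and np.isscalar(lat2):
        return float(d)
    return d


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, radians in [0, 2π)."""
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.mod(np.arctan2(y, x), 2.0 * np.pi)


def _as_utc(series: pd.Series) -> pd.Series:
    s = pd.to_datetime(series)
    if s.dt.tz is None:
        s = s.dt.tz_localize("UTC")
    else:
        s = s.dt.tz_convert("UTC")
    return s


def speed_filter(fixes: pd.DataFrame, vmax_ms: float = 20.0) -> pd.DataFrame:
    """Remove fixes implying a travel speed above ``vmax_ms`` (m s⁻¹).

    Forward pass from the first fix: whenever the speed from the last kept
    fix to the next fix exceeds the threshold, the *later* fix is dropped and
    the check continues from the same anchor — equivalent to iterating
    removal-and-recheck to a fixed point.  Idempotent; output is a
    subsequence of the input.
    """
    if len(fixes) == 0:
        return fixes.copy()
    df = fixes.reset_index(drop=True)
    t = _as_utc(df["time"]).to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    keep = [0]
    for i in range(1, len(df)):
        j = keep[-1]
        dt = t[i] - t[j]
        if dt <= 0:
            continue
        d_m = great_circle_km(lat[j], lon[j], lat[i], lon[i]) * 1000.0
        if d_m / dt <= vmax_ms:
            keep.append(i)
    return df.iloc[keep].reset_index(drop=True)


def regularize(
    fixes: pd.DataFrame,
    interval_min: float,
    max_gap: int = 4,
) -> pd.DataFrame:
    """Linearly interpolate fixes onto a uniform grid anchored at the first fix.

    Positions are interpolated in plain lat/lon (adequate at 10–20 min
    steps over foraging-trip scales).  Grid times falling inside a raw gap
    longer than ``max_gap × interval_min`` are emitted with NaN coordinates
    rather than inventing positions.  The original fix count is preserved in
    ``DataFrame.attrs["n_raw_fixes"]``.
    """
    df = fixes.reset_index(drop=True)
    if len(df) <= 1:
        if len(df) == 1:
            warnings.warn("regularize: single fix, returned unchanged")
        out = df.copy()
        out["interpolated"] = False
        out.attrs["n_raw_fixes"] = len(df)
        return out
    times = _as_utc(df["time"])
    t = times.to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    step = interval_min * 60.0
    n_steps = int(np.floor((t[-1] - t[0]) / step + 1e-9))
    grid = t[0] + step * np.arange(n_steps + 1)
    lat = np.interp(grid, t, df["lat"].to_numpy(float))
    lon = np.interp(grid, t, df["lon"].to_numpy(float))
    # mask grid points spanned by a raw gap longer than max_gap intervals
    idx_right = np.searchsorted(t, grid, side="left")
    idx_right = np.clip(idx_right, 1, len(t) - 1)
    gap = t[idx_right] - t[idx_right - 1]
    k = np.searchsorted(t, grid)
    kl = np.clip(k - 1, 0, len(t) - 1)
    kr = np.clip(k, 0, len(t) - 1)
    on_raw = (np.abs(t[kl] - grid) < 0.5) | (np.abs(t[kr] - grid) < 0.5)
    missing = (gap > max_gap * step) & ~on_raw
    lat[missing] = np.nan
    lon[missing] = np.nan
    out = pd.DataFrame(
        {
            "bird_id": df["bird_id"].iloc[0],
            "time": pd.to_datetime(grid * 1e9).tz_localize("UTC"),
            "lat": lat,
            "lon": lon,
            "interpolated": ~on_raw,
        }
    )
    out.attrs["n_raw_fixes"] = len(df)
    return out


@dataclass
class Trip:
    """One foraging trip: a contiguous at-sea run of fixes.

    ``complete`` means the run is bounded by at-colony fixes on both sides;
    incomplete trips (device died at sea) are retained but should only be
    used for the maximum-range metric.
    """

    bird_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    fixes: pd.DataFrame = field(repr=False)
    complete: bool = True
    stage: str | None = None
    duration_h: float = np.nan
    total_distance_km: float = np.nan
    max_range_km: float = np.nan
    trip_class: str = "none"

    def to_dict(self) -> dict:
        return {
            "bird_id": self.bird_id,
            "start": self.start,
            "end": self.end,
            "complete": self.complete,
            "stage": self.stage,
            "duration_h": self.duration_h,
            "total_distance_km": self.total_distance_km,
            "max_range_km": self.max_range_km,
            "trip_class": self.trip_class,
        }


def segment_trips(
    fixes: pd.DataFrame,
    colony: tuple[float, float],
    colony_radius_km: float = 1.0,
    stage: str | None = None,
) -> list[Trip]:
    """Cut a regularized track into foraging trips.

    A fix is "at colony" when within ``colony_radius_km`` of ``colony``
    (lat, lon).  Maximal runs of off-colony fixes become trips; a trip is
    complete iff flanked by at-colony fixes on both sides.  Missing
    (NaN-position) fixes inside a run stay with the run.
    """
    df = fixes.reset_index(drop=True)
    if len(df) == 0:
        return []
    valid = df["lat"].notna().to_numpy()
    dist = np.full(len(df), np.nan)
    dist[valid] = great_circle_km(
        df.loc[valid, "lat"].to_numpy(float),
        df.loc[valid, "lon"].to_numpy(float),
        colony[0],
        colony[1],
    )
    at_colony = valid & (dist <= colony_radius_km)
    trips: list[Trip] = []
    i = 0
    n = len(df)
    while i < n:
        if at_colony[i] or not valid[i]:
            i += 1
            continue
        j = i
        while j < n and not (valid[j] and at_colony[j]):
            j += 1
        left_ok = i > 0 and at_colony[i - 1]
        right_ok = j < n
        # include the flanking at-colony fixes (when present) so distance
        # integration covers the departure and return legs; start/end still
        # bound the off-colony run
        lo = i - 1 if left_ok else i
        hi = j + 1 if right_ok else j
        seg = df.iloc[lo:hi].reset_index(drop=True)
        run_times = _as_utc(df.iloc[i:j]["time"])
        trips.append(
            Trip(
                bird_id=str(seg["bird_id"].iloc[0]),
                start=run_times.iloc[0],
                end=run_times.iloc[-1],
                fixes=seg,
                complete=bool(left_ok and right_ok),
                stage=stage,
            )
        )
        i = j
    return trips


def trip_metrics(trip: Trip, colony: tuple[float, float]) -> Trip:
    """Fill duration, total-distance and max-range metrics in place."""
    seg = trip.fixes[trip.fixes["lat"].notna()]
    trip.duration_h = (trip.end - trip.start).total_seconds() / 3600.0
    if len(seg) >= 2:
        lat = seg["lat"].to_numpy(float)
        lon = seg["lon"].to_numpy(float)
        trip.total_distance_km = float(
            np.sum(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:]))
        )
    else:
        trip.total_distance_km = 0.0
    if len(seg) >= 1:
        trip.max_range_km = float(
            np.max(
                great_circle_km(
                    seg["lat"].to_numpy(float), seg["lon"].to_numpy(float), colony[0], colony[1]
                )
            )
        )
    return trip


def classify_trip(trip: Trip) -> str:
    """Short/long trip class for complete chick-rearing trips.

    Short = at most 2 days (48 h, boundary inclusive) at sea; long otherwise.
    Incubation and incomplete trips get class ``"none"``.
    """
    if trip.stage != "chick_rearing" or not trip.complete:
        trip.trip_class = "none"
    elif trip.duration_h <= SHORT_TRIP_MAX_H:
        trip.trip_class = "short"
    else:
        trip.trip_class = "long"
    return trip.trip_class


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """One-row-per-trip summary table."""
    return pd.DataFrame([t.to_dict() for t in trips])
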