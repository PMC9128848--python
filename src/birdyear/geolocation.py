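"""Threshold light-level geolocation from archival light loggers.

A geolocator records the maximum light intensity in each 5-minute interval.
The instants at which light crosses a calibrated threshold define morning
(sunrise) and evening (sunset) twilights.  From one sunrise/sunset pair the
method recovers:

* **longitude** from the timing of local apparent midday (or midnight),
  corrected by the equation of time — 15° of longitude per hour of offset
  from 12:00 UTC, east-positive;
* **latitude** from the day (or night) length, by solving the sunrise
  equation ``cos ω0 = (sin a0 − sin φ sin δ) / (cos φ cos δ)`` for φ, where
  ω0 is the half-day hour angle, δ the solar declination and a0 the
  calibrated sun elevation angle of the threshold crossing.

Near the equinoxes day length is ~12 h at every latitude, so light-derived
latitudes are unreliable; positions within a configurable window (default
±14 days) of either equinox are flagged.  Typical accuracy of the whole
method on real loggers is of the order of 186 ± 114 km.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import solar


def detect_twilights(
    light: pd.DataFrame,
    light_threshold: float,
    min_dark_min: float = 30.0,
) -> pd.DataFrame:
    """Locate sunrise/sunset threshold crossings in a light series.

    ``light`` has columns ``time`` (UTC) and ``light``.  Crossing times are
    linearly interpolated between adjacent samples; dark runs shorter than
    ``min_dark_min`` that are flanked by light (logger shading, e.g. a bird
    sitting on its tag) are ignored rather than read as a sunset/sunrise
    pair.

    Returns a frame of crossings: ``time`` (UTC), ``kind`` (``sunrise`` /
    ``sunset``).
    """
    df = light.dropna(subset=["light"]).reset_index(drop=True)
    if len(df) < 2:
        return pd.DataFrame(columns=["time", "kind"])
    t = pd.to_datetime(df["time"])
    if t.dt.tz is None:
        t = t.dt.tz_localize("UTC")
    tt = t.to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    vals = df["light"].to_numpy(float)
    above = vals >= light_threshold

    # close shading dips: dark runs shorter than min_dark flanked by light
    min_dark_s = min_dark_min * 60.0
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            j = i
            while j < n and not above[j]:
                j += 1
            flanked = i > 0 and j < n
            if flanked and (tt[j] - tt[i - 1]) < min_dark_s + 1e-9:
                above[i:j] = True
            i = j
        else:
            i += 1

    rows = []
    for k in range(1, n):
        if above[k] == above[k - 1]:
            continue
        lo, hi = vals[k - 1], vals[k]
        frac = 0.5 if hi == lo else (light_threshold - lo) / (hi - lo)
        frac = float(np.clip(frac, 0.0, 1.0))
        tc = tt[k - 1] + frac * (tt[k] - tt[k - 1])
        rows.append(
            {
                "time": pd.Timestamp(tc * 1e9, unit="ns", tz="UTC"),
                "kind": "sunrise" if above[k] else "sunset",
            }
        )
    return pd.DataFrame(rows)


def twilight_pairs(crossings: pd.DataFrame, max_day_h: float = 22.0) -> pd.DataFrame:
    """Pair crossings into days: each sunrise with the following sunset.

    Pairs implying a day longer than ``max_day_h`` are dropped (missed
    twilight).  Returns ``date, sunrise, sunset``.
    """
    rows = []
    cr = crossings.sort_values("time").reset_index(drop=True)
    for k in range(len(cr) - 1):
        if cr.loc[k, "kind"] == "sunrise" and cr.loc[k + 1, "kind"] == "sunset":
            rise, set_ = cr.loc[k, "time"], cr.loc[k + 1, "time"]
            if (set_ - rise).total_seconds() / 3600.0 <= max_day_h:
                rows.append({"date": rise.normalize(), "sunrise": rise, "sunset": set_})
    return pd.DataFrame(rows)


def _solve_latitude(
    day_length_h: float,
    declination: float,
    sun_angle: float,
    lat_hint: float | None,
) -> float:
    """Latitude whose day length (to the ``sun_angle`` horizon) matches.

    The sunrise equation can admit two roots in [−89°, 89°]; ties are broken
    toward ``lat_hint`` when given, otherwise the day is dropped (NaN).
    Returns NaN when no latitude reproduces the observed day length.
    """
    w0 = np.radians(day_length_h * 15.0 / 2.0)
    decl_r = np.radians(declination)
    a0_r = np.radians(sun_angle)

    def f(phi_deg: float) -> float:
        phi = np.radians(phi_deg)
        return (
            np.sin(phi) * np.sin(decl_r)
            + np.cos(phi) * np.cos(decl_r) * np.cos(w0)
            - np.sin(a0_r)
        )

    grid = np.linspace(-89.0, 89.0, 179)
    fg = np.array([f(p) for p in grid])
    roots = []
    for k in range(len(grid) - 1):
        if fg[k] == 0.0:
            roots.append(grid[k])
        elif fg[k] * fg[k + 1] < 0:
            roots.append(brentq(f, grid[k], grid[k + 1], xtol=1e-6))
    if not roots:
        return np.nan
    if len(roots) == 1:
        return float(roots[0])
    if lat_hint is None:
        return np.nan
    return float(min(roots, key=lambda r: abs(r - lat_hint)))


def threshold_position(
    sunrise: pd.Timestamp,
    sunset: pd.Timestamp,
    sun_angle: float,
    lat_hint: float | None = None,
    kind: str = "noon",
) -> dict:
    """One position from a twilight pair.

    For ``kind="noon"`` the pair is (sunrise, following sunset): longitude
    from the apparent local midday, latitude from the day length.  For
    ``kind="midnight"`` the pair is (sunset, following sunrise): longitude
    from apparent local midnight, latitude from the night length (via the
    complementary day length).  ``sun_angle`` is the calibrated solar
    elevation (degrees, typically negative) at the light threshold.
    """
    if kind == "noon":
        first, second = sunrise, sunset
    elif kind == "midnight":
        first, second = sunset, sunrise
    else:
        raise ValueError(f"kind must be 'noon' or 'midnight', got {kind!r}")
    if second <= first:
        raise ValueError("twilight pair out of order")
    mid = first + (second - first) / 2
    decl, eot = solar.solar_ephemeris(mid)
    mid_min = (
        mid.hour * 60.0 + mid.minute + mid.second / 60.0 + mid.microsecond / 6e7
    )
    if kind == "noon":
        lon = (720.0 - eot - mid_min) / 4.0
        day_h = (second - first).total_seconds() / 3600.0
    else:
        lon = (1440.0 - eot - mid_min) / 4.0
        day_h = 24.0 - (second - first).total_seconds() / 3600.0
    lon = float(np.mod(lon + 180.0, 360.0) - 180.0)
    lat = _solve_latitude(day_h, decl, sun_angle, lat_hint)
    return {"time": mid, "kind": kind, "lat": lat, "lon": lon}


def positions_from_light(
    light: pd.DataFrame,
    light_threshold: float,
    sun_angle: float,
    lat_hint: float | None = None,
    min_dark_min: float = 30.0,
) -> pd.DataFrame:
    """Full chain: twilights → noon and midnight positions, time-sorted.

    At most two positions per day (one noon, one midnight).  Output columns:
    ``time, kind, lat, lon, equinox_masked`` (mask flag all False; apply
    :func:`equinox_mask` afterwards).
    """
    crossings = detect_twilights(light, light_threshold, min_dark_min=min_dark_min)
    rows = []
    cr = crossings.sort_values("time").reset_index(drop=True)
    for k in range(len(cr) - 1):
        a, b = cr.loc[k], cr.loc[k + 1]
        span_h = (b["time"] - a["time"]).total_seconds() / 3600.0
        if span_h > 22.0:
            continue
        if a["kind"] == "sunrise" and b["kind"] == "sunset":
            rows.append(
                threshold_position(a["time"], b["time"], sun_angle, lat_hint, "noon")
            )
        elif a["kind"] == "sunset" and b["kind"] == "sunrise":
            rows.append(
                threshold_position(b["time"], a["time"], sun_angle, lat_hint, "midnight")
            )
    pos = pd.DataFrame(rows, columns=["time", "kind", "lat", "lon"])
    pos["equinox_masked"] = False
    return pos.sort_values("time").reset_index(drop=True)


def equinox_mask(positions: pd.DataFrame, window_days: float = 14.0) -> pd.DataFrame:
    """Flag positions within ``window_days`` of either equinox.

    Masked positions keep their longitude (useful for distance bookkeeping)
    but their latitude must be treated as unreliable; downstream spatial
    analyses drop them.
    """
    pos = positions.copy()
    if len(pos) == 0:
        pos["equinox_masked"] = pd.Series(dtype=bool)
        return pos
    t = pd.to_datetime(pos["time"])
    masked = np.zeros(len(pos), dtype=bool)
    for year in sorted(t.dt.year.unique()):
        for eq in solar.equinox_dates(int(year)):
            d = (t - eq).dt.total_seconds().abs() / 86400.0
            masked |= (d <= window_days).to_numpy()
    pos["equinox_masked"] = masked
    return pos


def calibrate_sun_angle(
    light: pd.DataFrame,
    site: tuple[float, float],
    light_threshold: float | None = None,
    min_days: int = 7,
    min_dark_min: float = 30.0,
) -> float:
    """Sun elevation angle of the light threshold, from light at a known site.

    Uses a span of light recorded at a known position (e.g. the colony
    before departure): the angle is the median solar elevation at the
    detected threshold crossings, computed at the true site.  The median
    makes the estimate robust to occasional shaded twilights.

    ``light_threshold`` defaults to the midpoint of the observed night floor
    and day ceiling (2nd / 98th percentiles).
    """
    if light_threshold is None:
        vals = light["light"].to_numpy(float)
        light_threshold = float(
            (np.nanpercentile(vals, 2) + np.nanpercentile(vals, 98)) / 2.0
        )
    crossings = detect_twilights(light, light_threshold, min_dark_min=min_dark_min)
    if len(crossings) == 0:
        raise ValueError("no twilights detected; record a longer calibration span")
    n_days = crossings["time"].dt.normalize().nunique()
    if n_days < min_days:
        raise ValueError(
            f"calibration needs at least {min_days} days of usable twilights, "
            f"got {n_days}; record a longer span at the known site"
        )
    elev = [
        solar.solar_elevation(ts, site[0], site[1]) for ts in crossings["time"]
    ]
    return float(np.median(elev))
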