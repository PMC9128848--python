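"""Low-precision solar ephemeris (declination, equation of time, elevation).

The formulae are the classic NOAA/Spencer Fourier fits, accurate to roughly
0.1° in declination and a fraction of a minute in the equation of time —
ample for threshold light-level geolocation, whose dominant error sources
(shading, weather, behaviour) are orders of magnitude larger.

Conventions: all angles in degrees unless suffixed ``_rad``; longitudes are
east-positive; times are timezone-aware UTC (``pandas.Timestamp`` /
``DatetimeIndex``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Default solar elevation of the visible sunrise/sunset horizon (degrees):
#: 16' solar radius + 34' standard atmospheric refraction.
HORIZON_DEG = -0.833


def _to_utc_index(times) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(pd.to_datetime(times))
    if idx.tz is None:
        idx = idx.tz_localize("UTC")
    else:
        idx = idx.tz_convert("UTC")
    return idx


def _fractional_year_rad(idx: pd.DatetimeIndex) -> np.ndarray:
    year_days = np.where(idx.is_leap_year, 366.0, 365.0)
    frac_hour = idx.hour + idx.minute / 60.0 + idx.second / 3600.0
    return 2.0 * np.pi / year_days * (idx.dayofyear - 1 + (frac_hour - 12.0) / 24.0)


def solar_ephemeris(times):
    """Solar declination (degrees) and equation of time (minutes).

    Parameters
    ----------
    times
        Scalar or array-like of UTC timestamps.

    Returns
    -------
    declination : ndarray or float
        Apparent solar declination, degrees, in [-23.45, 23.45] ± 0.1.
    equation_of_time : ndarray or float
        Apparent minus mean solar time, minutes, |EoT| ≤ 17 min.
    """
    scalar = np.isscalar(times) or isinstance(times, (pd.Timestamp, str))
    idx = _to_utc_index([times] if scalar else times)
    g = _fractional_year_rad(idx)
    eot = 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )
    decl_rad = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    decl = np.degrees(decl_rad)
    if scalar:
        return float(decl[0]), float(eot[0])
    return decl, eot


def solar_elevation(times, lat: float, lon: float):
    """Solar elevation angle (degrees) at a site, no refraction correction.

    ``lat``/``lon`` in signed decimal degrees WGS84 (east-positive).
    """
    scalar = np.isscalar(times) or isinstance(times, (pd.Timestamp, str))
    idx = _to_utc_index([times] if scalar else times)
    decl, eot = solar_ephemeris(idx)
    minutes = idx.hour * 60.0 + idx.minute + idx.second / 60.0
    # true solar time in minutes; 4 minutes of time per degree of longitude
    tst = minutes + eot + 4.0 * lon
    hour_angle = np.radians(tst / 4.0 - 180.0)
    lat_r, decl_r = np.radians(lat), np.radians(decl)
    sin_elev = np.sin(lat_r) * np.sin(decl_r) + np.cos(lat_r) * np.cos(decl_r) * np.cos(
        hour_angle
    )
    elev = np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    if scalar:
        return float(elev[0])
    return elev


def day_length_hours(date, lat: float, sun_angle: float = HORIZON_DEG) -> float:
    """Day length (hours) at ``lat`` for the given date and horizon angle.

    Solves cos ω0 = (sin a0 − sin φ sin δ) / (cos φ cos δ) for the half-day
    hour angle ω0.  Returns 24.0 (0.0) when the sun never sets (rises).
    """
    noon = pd.Timestamp(date).normalize() + pd.Timedelta(hours=12)
    if noon.tz is None:
        noon = noon.tz_localize("UTC")
    decl, _ = solar_ephemeris(noon)
    lat_r, decl_r, a0_r = map(np.radians, (lat, decl, sun_angle))
    cos_w0 = (np.sin(a0_r) - np.sin(lat_r) * np.sin(decl_r)) / (
        np.cos(lat_r) * np.cos(decl_r)
    )
    if cos_w0 <= -1.0:
        return 24.0
    if cos_w0 >= 1.0:
        return 0.0
    return float(2.0 * np.degrees(np.arccos(cos_w0)) / 15.0)


def equinox_dates(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """March and September equinox instants for ``year``.

    Located as the zero crossings of the declination computed by
    :func:`solar_ephemeris` (not a hardcoded calendar date), refined by
    bisection to about a minute.
    """
    out = []
    for lo_day, hi_day in ((60, 110), (240, 290)):
        lo = pd.Timestamp(year=year, month=1, day=1, tz="UTC") + pd.Timedelta(
            days=lo_day
        )
        hi = pd.Timestamp(year=year, month=1, day=1, tz="UTC") + pd.Timedelta(
            days=hi_day
        )
        f_lo = solar_ephemeris(lo)[0]
        for _ in range(40):
            mid = lo + (hi - lo) / 2
            f_mid = solar_ephemeris(mid)[0]
            if (f_lo < 0) == (f_mid < 0):
                lo, f_lo = mid, f_mid
            else:
                hi = mid
        out.append(lo + (hi - lo) / 2)
    return out[0], out[1]
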