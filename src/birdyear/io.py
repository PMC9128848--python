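"""CSV readers/writers with schema validation, and the run configuration.

All tables are plain CSV with a declared header and ISO-8601 UTC
timestamps.  Readers validate column presence and per-row ranges, reporting
malformed rows with their line numbers; writers round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    pass


def _parse_times(df: pd.DataFrame, col: str, path: str) -> pd.DataFrame:
    try:
        t = pd.to_datetime(df[col], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: bad {col} timestamps: {exc}") from None
    df[col] = t
    return df


def _require(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _check_rows(df: pd.DataFrame, bad: pd.Series, path: str, what: str) -> None:
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()[:10]
        raise SchemaError(f"{path}: {what} at line(s) {lines}")


def read_fixes(path) -> pd.DataFrame:
    """GPS fix table: ``bird_id,time,lat,lon``."""
    df = pd.read_csv(path)
    _require(df, ["bird_id", "time", "lat", "lon"], str(path))
    df = _parse_times(df, "time", str(path))
    _check_rows(df, ~df["lat"].between(-90, 90), str(path), "latitude out of [-90, 90]")
    _check_rows(
        df,
        ~((df["lon"] > -180) & (df["lon"] <= 180)),
        str(path),
        "longitude out of (-180, 180]",
    )
    return df


def write_fixes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_light(path) -> pd.DataFrame:
    """Light series: ``time,light`` (5-min maxima)."""
    df = pd.read_csv(path)
    _require(df, ["time", "light"], str(path))
    return _parse_times(df, "time", str(path))


def read_activity(path) -> pd.DataFrame:
    """Immersion samples: ``time,wet`` with wet ∈ {0, 1}."""
    df = pd.read_csv(path)
    _require(df, ["time", "wet"], str(path))
    df = _parse_times(df, "time", str(path))
    _check_rows(df, ~df["wet"].isin([0, 1]), str(path), "wet flag not 0/1")
    return df


def read_positions(path) -> pd.DataFrame:
    """Geolocation positions: ``time,kind,lat,lon,equinox_masked``."""
    df = pd.read_csv(path)
    _require(df, ["time", "kind", "lat", "lon"], str(path))
    df = _parse_times(df, "time", str(path))
    if "equinox_masked" not in df.columns:
        df["equinox_masked"] = False
    df["equinox_masked"] = df["equinox_masked"].astype(bool)
    return df


def write_positions(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_isotopes(path) -> pd.DataFrame:
    """Isotope samples: ``bird_id,tissue,period,year,d13C,d15N[,corrected]``."""
    df = pd.read_csv(path)
    _require(df, ["bird_id", "tissue", "period", "d13C", "d15N"], str(path))
    _check_rows(
        df,
        ~np.isfinite(df["d13C"]) | ~np.isfinite(df["d15N"]),
        str(path),
        "non-finite delta value",
    )
    if "corrected" not in df.columns:
        df["corrected"] = False
    return df


@dataclass
class RunConfig:
    """All pipeline thresholds and settings in one auditable place.

    Defaults are the standard study conditions: 20 / 10-min GPS intervals
    for incubation / chick-rearing, a 20 m s⁻¹ speed filter, 48 h
    short/long trip split, 200 km / 8 h attendance rule, >90% daily wet
    fraction for moult, ±14 d equinox masking, kernel h = 0.2° on 0.1°
    cells for GPS and h = 1.8° on 1° cells for geolocation tracks.
    """

    colony: tuple[float, float] = (-39.25, 146.5)
    interval_min: dict = field(
        default_factory=lambda: {"incubation": 20.0, "chick_rearing": 10.0}
    )
    vmax_ms: float = 20.0
    colony_radius_km: float = 1.0
    max_gap_intervals: int = 4
    short_trip_max_h: float = 48.0
    attendance_max_dist_km: float = 200.0
    attendance_min_dry_h: float = 8.0
    moult_wet_threshold: float = 0.9
    equinox_window_days: float = 14.0
    kernel: dict = field(
        default_factory=lambda: {
            "gps": {"h": 0.2, "cell": 0.1},
            "gls": {"h": 1.8, "cell": 1.0},
        }
    )
    sun_angle: float | None = None  # calibrated at run time when None
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["colony"] = list(self.colony)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "colony" in d:
            d["colony"] = tuple(d["colony"])
        cfg = cls(**d)
        for name in (
            "vmax_ms",
            "colony_radius_km",
            "short_trip_max_h",
            "attendance_max_dist_km",
            "attendance_min_dry_h",
            "moult_wet_threshold",
            "equinox_window_days",
        ):
            if getattr(cfg, name) <= 0:
                raise SchemaError(f"config threshold {name} must be positive")
        return cfg
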