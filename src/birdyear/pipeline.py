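"""End-to-end pipelines tying the analysis stages together.

Two pipelines mirror the two halves of the tracking year:

* **breeding** (GPS): speed filter → regularize → trip segmentation →
  trip metrics and short/long classes → step metrics → EM binary
  clustering → behaviour proportions → per-class kernel UDs and pairwise
  Bhattacharyya overlap;
* **nonbreeding** (GLS): sun-angle calibration at the colony → twilight
  detection → threshold positions → equinox masking → activity blocks →
  moult window → burrow attendance → breeding boundaries → migration
  summary → kernel UD of retained positions.

Each run returns an artefact bundle (plain dict) and a manifest that echoes
every parameter and logs per-stage counts, so a rerun with the same inputs
and config is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from . import behaviour, geolocation, gps, phenology, spaceuse
from .io import RunConfig

logger = logging.getLogger("birdyear")


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()[:16]


def run_breeding(
    fixes: pd.DataFrame, config: RunConfig, stage: str = "chick_rearing"
) -> dict:
    """Breeding-season GPS pipeline for one deployment stage."""
    interval = config.interval_min[stage]
    manifest: dict = {
        "pipeline": "breeding",
        "stage": stage,
        "config": {
            "colony": list(config.colony),
            "interval_min": interval,
            "vmax_ms": config.vmax_ms,
            "colony_radius_km": config.colony_radius_km,
            "short_trip_max_h": config.short_trip_max_h,
            "kernel": config.kernel["gps"],
            "seed": config.seed,
        },
        "inputs": {"fixes": _checksum(fixes), "n_fixes": len(fixes)},
    }
    bundles: dict = {"manifest": manifest}

    filtered = gps.speed_filter(fixes, config.vmax_ms)
    manifest["speed_filter_removed"] = len(fixes) - len(filtered)
    logger.info("speed filter: %d fixes in, %d removed", len(fixes), manifest["speed_filter_removed"])

    regular = gps.regularize(filtered, interval, config.max_gap_intervals)
    trips = gps.segment_trips(
        regular, config.colony, config.colony_radius_km, stage=stage
    )
    for t in trips:
        gps.trip_metrics(t, config.colony)
        gps.classify_trip(t)
    manifest["n_trips"] = len(trips)
    manifest["n_complete_trips"] = sum(t.complete for t in trips)
    logger.info("segmented %d trips (%d complete)", len(trips), manifest["n_complete_trips"])
    bundles["trips"] = trips
    bundles["trip_table"] = gps.trips_to_frame(trips)

    # steps are computed per trip so colony sits do not contribute
    step_frames = []
    for k, t in enumerate(trips):
        s = behaviour.step_metrics(t.fixes)
        if len(s):
            s["trip_id"] = k
            s["dt_s"] = interval * 60.0
            step_frames.append(s)
    steps = (
        pd.concat(step_frames, ignore_index=True)
        if step_frames
        else pd.DataFrame(
            columns=["bird_id", "time", "lat", "lon", "speed_ms", "turn_rad", "state", "trip_id", "dt_s"]
        )
    )
    model = behaviour.embc_fit(steps)
    steps = behaviour.embc_classify(steps, model)
    per_trip, pooled = behaviour.behaviour_proportions(steps)
    bundles["steps"] = steps
    bundles["model"] = model
    bundles["behaviour_per_trip"] = per_trip
    bundles["behaviour_pooled"] = pooled
    manifest["embc"] = model.to_dict()

    kern = config.kernel["gps"]
    classes = sorted({t.trip_class for t in trips if t.trip_class != "none"} or {"all"})
    uds: dict = {}
    pts_all = pd.concat([t.fixes for t in trips if t.complete], ignore_index=True)
    extent = (
        pts_all["lat"].min() - 3 * kern["h"],
        pts_all["lat"].max() + 3 * kern["h"],
        pts_all["lon"].min() - 3 * kern["h"],
        pts_all["lon"].max() + 3 * kern["h"],
    )
    for cls in classes:
        pts = pd.concat(
            [
                t.fixes
                for t in trips
                if t.complete and (cls == "all" or t.trip_class == cls)
            ],
            ignore_index=True,
        )
        if len(pts) == 0:
            continue
        ud = spaceuse.kernel_ud(pts, kern["h"], kern["cell"], extent=extent)
        uds[cls] = {"ud": ud, "contours": spaceuse.ud_contours(ud)}
    bundles["uds"] = uds
    ba = {}
    keys = list(uds)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ba[f"{keys[i]}|{keys[j]}"] = spaceuse.ba_overlap(
                uds[keys[i]]["ud"], uds[keys[j]]["ud"]
            )
    bundles["ba"] = ba
    manifest["ba"] = ba
    return bundles


def run_nonbreeding(
    light: pd.DataFrame,
    activity: pd.DataFrame,
    config: RunConfig,
    calibration_span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
) -> dict:
    """Non-breeding GLS pipeline: geolocation, phenology, migration, UD."""
    manifest: dict = {
        "pipeline": "nonbreeding",
        "config": {
            "colony": list(config.colony),
            "attendance_max_dist_km": config.attendance_max_dist_km,
            "attendance_min_dry_h": config.attendance_min_dry_h,
            "moult_wet_threshold": config.moult_wet_threshold,
            "equinox_window_days": config.equinox_window_days,
            "kernel": config.kernel["gls"],
            "seed": config.seed,
        },
        "inputs": {
            "light": _checksum(light),
            "activity": _checksum(activity),
        },
    }
    bundles: dict = {"manifest": manifest}

    vals = light["light"].to_numpy(float)
    threshold = float((np.nanpercentile(vals, 2) + np.nanpercentile(vals, 98)) / 2.0)
    manifest["light_threshold"] = threshold

    sun_angle = config.sun_angle
    if sun_angle is None:
        if calibration_span is None:
            raise ValueError(
                "missing input: either a calibrated sun_angle in the config or a "
                "calibration span of light at the colony"
            )
        t = pd.to_datetime(light["time"], utc=True)
        cal = light[(t >= calibration_span[0]) & (t <= calibration_span[1])]
        sun_angle = geolocation.calibrate_sun_angle(
            cal, config.colony, light_threshold=threshold
        )
    manifest["sun_angle"] = sun_angle

    positions = geolocation.positions_from_light(
        light, threshold, sun_angle, lat_hint=config.colony[0]
    )
    positions = geolocation.equinox_mask(positions, config.equinox_window_days)
    manifest["n_positions"] = len(positions)
    manifest["n_equinox_masked"] = int(positions["equinox_masked"].sum())
    logger.info(
        "geolocation: %d positions, %d equinox-masked",
        len(positions), manifest["n_equinox_masked"],
    )
    bundles["positions"] = positions

    blocks, daily = phenology.block_activity(activity)
    bundles["blocks"], bundles["daily_wet"] = blocks, daily
    moult = phenology.detect_moult_window(daily, config.moult_wet_threshold)
    bundles["moult_window"] = moult
    manifest["moult_window"] = (
        None if moult is None else [str(moult[0].date()), str(moult[1].date())]
    )

    events = phenology.detect_attendance(
        blocks,
        positions,
        config.colony,
        light=light,
        light_threshold=threshold,
        max_dist_km=config.attendance_max_dist_km,
        min_dry_h=config.attendance_min_dry_h,
    )
    bundles["attendance"] = events
    manifest["n_attendance_events"] = len(events)
    boundaries = phenology.breeding_boundaries(events)
    bundles["boundaries"] = boundaries
    migration = phenology.migration_summary(positions, boundaries, config.colony)
    bundles["migration"] = migration
    manifest["migration"] = {
        "departure": str(boundaries[0].date()),
        "first_return": None if boundaries[1] is None else str(boundaries[1].date()),
        "duration_d": migration.duration_d,
        "total_distance_km": migration.total_distance_km,
        "max_range_km": migration.max_range_km,
    }

    kern = config.kernel["gls"]
    retained = positions[positions["lat"].notna() & ~positions["equinox_masked"]]
    ud = spaceuse.kernel_ud(retained, kern["h"], kern["cell"], source="gls")
    bundles["ud"] = {"ud": ud, "contours": spaceuse.ud_contours(ud)}
    return bundles


def manifest_json(bundle: dict) -> str:
    """Canonical JSON form of a run manifest (stable key order)."""
    return json.dumps(bundle["manifest"], sort_keys=True, default=str)
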