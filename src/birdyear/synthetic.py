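"""Synthetic bird-year generator with known ground truth.

Every downstream stage (trip segmentation, movement-state clustering,
light-level geolocation, immersion phenology, space use, isotopes) is
testable without field data by simulating a small pelagic seabird breeding
on an island colony in Bass Strait:

* **GPS phase** — a discrete-time, four-state correlated random walk on a
  local tangent plane around the colony.  States follow a Markov chain over
  the canonical regimes LL (rest), LH (intensive search), HL (travel),
  HH (extensive search); each state has its own speed distribution and
  turning-angle concentration.  A homing pull forces each trip to return to
  the colony once its duration budget elapses, so trips are segmentable
  ground truth.
* **GLS phase** — daily positions follow a scripted post-breeding migration
  (rapid outward leg to a distal wintering area ~2000 km west-southwest,
  a stationary period containing a flight-feather moult, a return leg, then
  residence near the colony with occasional burrow-attendance nights).
  Light is a logistic function of solar elevation at the true position with
  optional noise and shading; immersion samples every 30 s follow the
  behavioural regime (wet fraction > 90%/day in moult, 100% dry during
  attendance).
* **Isotopes** — bivariate-normal (δ¹³C, δ¹⁵N) groups per tissue/period.

Turn concentrations are von Mises κ about a zero turn; a *negative* κ
concentrates turns near ±π (tortuous doubling-back), which is how the
high-turn searching states are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .behaviour import STATES
from .gps import EARTH_RADIUS_KM, great_circle_km
from . import solar

KM_PER_DEG = 111.19493


def _default_transition(p_stay: float = 0.85,
                        occupancy: tuple[float, ...] = (0.35, 0.12, 0.46, 0.07)) -> np.ndarray:
    """Row-stochastic matrix with given self-persistence and stationary mix.

    Off-diagonal mass of row i is spread over j ≠ i proportionally to the
    target occupancy, which makes ``occupancy`` the stationary distribution.
    """
    pi = np.asarray(occupancy, dtype=float)
    pi = pi / pi.sum()
    m = np.zeros((4, 4))
    for i in range(4):
        m[i, i] = p_stay
        off = pi.copy()
        off[i] = 0.0
        m[i] = m[i] + (1.0 - p_stay) * off / off.sum()
    return m


@dataclass
class SimConfig:
    """Study conditions for the simulated bird-year.

    State order everywhere is (LL, LH, HL, HH).  Speeds are in m s⁻¹, the
    turn concentration is a von Mises κ (negative κ concentrates turns near
    π, i.e. a high-turn state), light units are an arbitrary logger scale.
    """

    colony: tuple[float, float] = (-39.25, 146.5)
    start_time: str = "2019-11-15T00:00:00Z"
    duration_days: float = 12.0
    gps_interval_min: float = 10.0
    state_transition: np.ndarray = dc_field(default_factory=_default_transition)
    state_speed_mean: tuple[float, ...] = (0.3, 1.0, 10.0, 6.5)
    state_speed_sd: tuple[float, ...] = (0.15, 0.3, 1.2, 1.0)
    state_turn_concentration: tuple[float, ...] = (30.0, -2.0, 30.0, -2.0)
    trip_duration_h: float = 30.0
    colony_stay_h: float = 10.0
    colony_radius_km: float = 1.0
    # light model
    light_max_units: float = 64.0
    light_inflection_deg: float = -3.5
    light_steepness: float = 1.2
    light_noise_sd: float = 1.0
    shading_prob: float = 0.05
    # immersion model: per-state probability a 30-s sample is wet
    state_wet_prob: tuple[float, ...] = (0.95, 0.75, 0.05, 0.35)
    seed: int = 0

    def validate(self) -> None:
        m = np.asarray(self.state_transition, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("state_transition must be 4×4")
        for i, row in enumerate(m):
            if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"state_transition row {i} ({STATES[i]}) is not a probability "
                    f"distribution (sum {row.sum():.6g})"
                )
        if any(s < 0 for s in self.state_speed_mean) or any(
            s < 0 for s in self.state_speed_sd
        ):
            raise ValueError("state speeds must be non-negative")
        if not (0.0 <= self.shading_prob <= 1.0):
            raise ValueError("shading_prob must be in [0, 1]")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each simulated data stream."""

    states: pd.Series | None = None           # per-fix true label (or "colony")
    trips: list[tuple[pd.Timestamp, pd.Timestamp]] = dc_field(default_factory=list)
    daily_positions: pd.DataFrame | None = None  # date, lat, lon (GLS phase)
    daily_regime: pd.Series | None = None     # date -> regime name
    moult_interval: tuple[pd.Timestamp, pd.Timestamp] | None = None
    attendance_events: list[tuple[pd.Timestamp, pd.Timestamp]] = dc_field(
        default_factory=list
    )
    last_attendance: pd.Timestamp | None = None
    first_return: pd.Timestamp | None = None


def completed_trips(truth: TruthRecord) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Truth trips that returned to the colony (end fix labelled 'colony')."""
    return [
        (t0, t1) for t0, t1 in truth.trips if truth.states.loc[t1] == "colony"
    ]


def _xy_to_latlon(x_km, y_km, colony):
    lat = colony[0] + np.asarray(y_km) / KM_PER_DEG
    lon = colony[1] + np.asarray(x_km) / (KM_PER_DEG * np.cos(np.radians(colony[0])))
    return lat, lon


def simulate_track(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Four-state correlated-random-walk GPS track from the colony.

    Fixes are emitted at ``gps_interval_min`` spacing (inclusive endpoints).
    Within a trip the state follows the Markov chain; each step draws a
    speed from its state's normal distribution (truncated at 0) and updates
    the heading by a von Mises turn.  When a trip's duration budget elapses
    a homing pull (travel-state speed, heading at the colony) brings the
    bird back; at the colony it sits for ``colony_stay_h`` before departing
    again.  Identical seeds give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt_s = config.gps_interval_min * 60.0
    n = int(round(config.duration_days * 86400.0 / dt_s)) + 1
    t0 = pd.Timestamp(config.start_time)
    if t0.tz is None:
        t0 = t0.tz_localize("UTC")
    times = t0 + pd.to_timedelta(np.arange(n) * dt_s, unit="s")
    trans = np.asarray(config.state_transition, dtype=float)

    x = np.zeros(n)
    y = np.zeros(n)
    labels = np.empty(n, dtype=object)
    trips: list[tuple[pd.Timestamp, pd.Timestamp]] = []

    phase = "colony"  # colony | trip | homing
    stay_left = config.colony_stay_h * 3600.0 / 2.0  # first stay: half
    state = 2  # depart travelling (HL)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    budget_left = 0.0
    trip_start: pd.Timestamp | None = None
    labels[0] = "colony"

    for i in range(1, n):
        if phase == "colony":
            stay_left -= dt_s
            x[i], y[i] = 0.0, 0.0
            labels[i] = "colony"
            if stay_left <= 0.0:
                phase = "trip"
                budget_left = rng.uniform(0.6, 1.4) * config.trip_duration_h * 3600.0
                state = 2  # leave in travel mode
                heading = rng.uniform(0.0, 2.0 * np.pi)
                trip_start = times[i]
            continue

        guard_km = 8.0  # outbound guard: no mid-trip re-entry near the colony
        mode = "free"
        if phase == "trip":
            budget_left -= dt_s
            dist_home = np.hypot(x[i - 1], y[i - 1])
            if budget_left <= 0.0:
                phase = "homing"
            elif dist_home < guard_km:
                state = 2  # push outward in travel mode until clear
                mode = "outbound"
            else:
                state = rng.choice(4, p=trans[state])
        if phase == "homing":
            state = 2
            mode = "homing"

        kappa = config.state_turn_concentration[state]
        if mode == "homing":
            heading = np.arctan2(-x[i - 1], -y[i - 1]) + rng.vonmises(0.0, 50.0)
        elif mode == "outbound" and np.hypot(x[i - 1], y[i - 1]) > 1e-9:
            heading = np.arctan2(x[i - 1], y[i - 1]) + rng.vonmises(0.0, 50.0)
        elif abs(kappa) < 1e-12:
            heading = heading + rng.uniform(-np.pi, np.pi)
        elif kappa > 0:
            heading = heading + rng.vonmises(0.0, kappa)
        else:
            heading = heading + rng.vonmises(np.pi, -kappa)
        speed = max(
            0.0, rng.normal(config.state_speed_mean[state], config.state_speed_sd[state])
        )
        step_km = speed * dt_s / 1000.0
        if phase == "homing" and np.hypot(x[i - 1], y[i - 1]) <= step_km:
            # final homing step lands exactly on the colony (never overshoots)
            x[i], y[i] = 0.0, 0.0
            labels[i] = "colony"
            trips.append((trip_start, times[i]))
            phase = "colony"
            stay_left = rng.uniform(0.6, 1.4) * config.colony_stay_h * 3600.0
            continue
        x[i] = x[i - 1] + step_km * np.sin(heading)
        y[i] = y[i - 1] + step_km * np.cos(heading)
        labels[i] = STATES[state]
        if phase == "homing" and np.hypot(x[i], y[i]) <= config.colony_radius_km:
            # close enough to count as arrived: first at-colony fix ends the trip
            x[i], y[i] = 0.0, 0.0
            labels[i] = "colony"
            trips.append((trip_start, times[i]))
            phase = "colony"
            stay_left = rng.uniform(0.6, 1.4) * config.colony_stay_h * 3600.0

    if phase in ("trip", "homing") and trip_start is not None and labels[n - 1] != "colony":
        trips.append((trip_start, times[n - 1]))  # incomplete trailing trip

    lat, lon = _xy_to_latlon(x, y, config.colony)
    fixes = pd.DataFrame(
        {"bird_id": "sim01", "time": times, "lat": lat, "lon": lon}
    )
    truth = TruthRecord(states=pd.Series(labels, index=times), trips=trips)
    return fixes, truth


def simulate_light(
    daily_positions: pd.DataFrame, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Light series: 5-minute maxima from a saturating solar-elevation curve.

    ``daily_positions`` has columns ``date, lat, lon`` (one row per day;
    the position holds for the whole UTC day).  Light is a logistic in the
    solar elevation with inflection at the calibration angle — so the
    half-scale threshold crossing happens exactly at
    ``light_inflection_deg`` — plus Gaussian noise; daytime samples are
    darkened with probability ``shading_prob``.  Days absent from
    ``daily_positions`` are emitted with missing light.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    dp = daily_positions.copy()
    dp["date"] = pd.to_datetime(dp["date"])
    if dp["date"].dt.tz is None:
        dp["date"] = dp["date"].dt.tz_localize("UTC")
    dp = dp.set_index("date").sort_index()
    start = dp.index.min()
    end = dp.index.max() + pd.Timedelta(days=1)
    idx = pd.date_range(start, end, freq="5min", inclusive="left")
    light = np.full(len(idx), np.nan)
    for day, grp in pd.Series(np.arange(len(idx)), index=idx).groupby(
        idx.normalize()
    ):
        if day not in dp.index:
            continue  # no position for this day: emitted all-missing
        lat, lon = dp.loc[day, "lat"], dp.loc[day, "lon"]
        elev = solar.solar_elevation(grp.index, float(lat), float(lon))
        val = config.light_max_units / (
            1.0
            + np.exp(-config.light_steepness * (elev - config.light_inflection_deg))
        )
        if config.light_noise_sd > 0:
            val = val + rng.normal(0.0, config.light_noise_sd, len(val))
        if config.shading_prob > 0:
            shade = (elev > 0) & (rng.random(len(val)) < config.shading_prob)
            val = np.where(shade, val * rng.uniform(0.0, 0.1, len(val)), val)
        light[grp.to_numpy()] = np.clip(val, 0.0, config.light_max_units)
    return pd.DataFrame({"time": idx, "light": light})


_REGIME_WET_PROB = {
    "colony": 0.5,
    "outward": 0.3,
    "distal": 0.7,
    "return": 0.3,
    "residence": 0.55,
}

MOULT_WET_PROB = 0.97


def simulate_activity(
    truth: TruthRecord,
    config: SimConfig,
    span: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Immersion (wet/dry) samples every 30 s driven by the ground truth.

    Sample-wise wet probability, in priority order: attendance events are
    100% dry; days inside the moult interval are wet with probability
    ``MOULT_WET_PROB`` (daily wet fraction > 0.9 by construction); otherwise
    the per-day regime (GLS phase) or the per-fix behavioural state (GPS
    phase) sets the probability — resting LL is mostly wet, travelling HL
    mostly dry.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if span is None:
        if truth.daily_regime is not None:
            start = pd.Timestamp(truth.daily_regime.index.min())
            end = pd.Timestamp(truth.daily_regime.index.max()) + pd.Timedelta(days=1)
        elif truth.states is not None:
            start, end = truth.states.index[0], truth.states.index[-1]
        else:
            raise ValueError("truth carries neither daily regimes nor fix states")
    else:
        start, end = span
    idx = pd.date_range(start, end, freq="30s", inclusive="left")
    p = np.full(len(idx), 0.5)

    if truth.states is not None:
        # nearest-fix state probability over the GPS span
        fix_t = truth.states.index.asi8
        wet_probs = dict(zip(STATES, config.state_wet_prob))
        state_p = truth.states.map({**wet_probs, "colony": 0.0}).to_numpy(float)
        pos = np.clip(np.searchsorted(fix_t, idx.asi8), 0, len(fix_t) - 1)
        in_gps = (idx >= truth.states.index[0]) & (idx <= truth.states.index[-1])
        p[in_gps] = state_p[pos[in_gps]]

    if truth.daily_regime is not None:
        days = idx.normalize()
        regime = truth.daily_regime.reindex(days)
        known = regime.notna().to_numpy()
        p[known] = regime[known].map(_REGIME_WET_PROB).to_numpy(float)

    if truth.moult_interval is not None:
        m0, m1 = truth.moult_interval
        in_moult = (idx >= m0) & (idx < m1 + pd.Timedelta(days=1))
        p[in_moult] = MOULT_WET_PROB

    for a, b in truth.attendance_events:
        p[(idx >= a) & (idx < b)] = 0.0

    wet = (rng.random(len(idx)) < p).astype(int)
    return pd.DataFrame({"time": idx, "wet": wet})


def simulate_isotopes(
    group_means: dict,
    group_cov: dict,
    n_per_group: dict | int,
    seed: int = 0,
) -> pd.DataFrame:
    """Bivariate-normal (δ¹³C, δ¹⁵N) samples per tissue/period group.

    ``group_means`` maps ``(tissue, period)`` to a (δ¹³C, δ¹⁵N) mean;
    ``group_cov`` to a 2×2 covariance (must be positive-definite).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for key, mean in group_means.items():
        tissue, period = key
        cov = np.asarray(group_cov[key], dtype=float)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"covariance for group {key} is not positive-definite"
            ) from None
        n = n_per_group if isinstance(n_per_group, int) else n_per_group[key]
        xy = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        for j in range(n):
            rows.append(
                {
                    "bird_id": f"{tissue[:2]}{period[:2]}{j:03d}",
                    "tissue": tissue,
                    "period": period,
                    "year": "sim",
                    "d13C": xy[j, 0],
                    "d15N": xy[j, 1],
                    "corrected": False,
                }
            )
    return pd.DataFrame(
        rows, columns=["bird_id", "tissue", "period", "year", "d13C", "d15N", "corrected"]
    )


#: Default isotope study conditions: blood in breeding, feathers after.
DEFAULT_ISOTOPE_GROUPS = {
    ("blood", "incubation"): (-18.9, 12.6),
    ("blood", "chick_rearing"): (-20.6, 11.0),
    ("feather", "non_breeding"): (-18.0, 12.2),
}
DEFAULT_ISOTOPE_COV = {
    ("blood", "incubation"): [[0.64, 0.1], [0.1, 1.0]],
    ("blood", "chick_rearing"): [[0.16, 0.05], [0.05, 0.49]],
    ("feather", "non_breeding"): [[0.64, 0.2], [0.2, 4.0]],
}


def simulate_gls_year(
    config: SimConfig,
    gls_start: str = "2020-01-10T00:00:00Z",
    pre_departure_days: int = 10,
    outward_days: int = 8,
    distal_days: int = 75,
    return_days: int = 8,
    total_days: int = 240,
    outward_km_per_day: float = 250.0,
    outward_bearing_deg: float = 245.0,
    moult_days: int = 30,
    moult_lag_days: int = 10,
    n_residence_attendance: int = 5,
) -> TruthRecord:
    """Scripted non-breeding-year ground truth (daily positions + phenology).

    The bird sits at the colony for ``pre_departure_days`` (nightly burrow
    attendance — the calibration span for geolocation), migrates out at
    ``outward_km_per_day`` on ``outward_bearing_deg``, winters at the distal
    site (with a ``moult_days`` flight-feather moult starting
    ``moult_lag_days`` after arrival), returns, and then resides ~100 km
    west of the colony with ``n_residence_attendance`` single-night burrow
    visits roughly every 12 days.
    """
    rng = np.random.default_rng(config.seed + 3)
    t0 = pd.Timestamp(gls_start)
    if t0.tz is None:
        t0 = t0.tz_localize("UTC")
    t0 = t0.normalize()
    days = pd.date_range(t0, periods=total_days, freq="D")
    lat = np.zeros(total_days)
    lon = np.zeros(total_days)
    regime = np.empty(total_days, dtype=object)
    colony = config.colony

    br = np.radians(outward_bearing_deg)
    step_lat = outward_km_per_day * np.cos(br) / KM_PER_DEG
    step_lon = outward_km_per_day * np.sin(br) / (
        KM_PER_DEG * np.cos(np.radians(colony[0]))
    )
    d_out_end = pre_departure_days + outward_days
    d_dist_end = d_out_end + distal_days
    d_ret_end = d_dist_end + return_days
    distal = (
        colony[0] + outward_days * step_lat,
        colony[1] + outward_days * step_lon,
    )
    residence = (colony[0] - 0.3, colony[1] - 1.3)  # ~100 km west-southwest

    for d in range(total_days):
        if d < pre_departure_days:
            lat[d], lon[d] = colony
            regime[d] = "colony"
        elif d < d_out_end:
            k = d - pre_departure_days + 1
            lat[d] = colony[0] + k * step_lat
            lon[d] = colony[1] + k * step_lon
            regime[d] = "outward"
        elif d < d_dist_end:
            lat[d] = distal[0] + rng.normal(0.0, 0.25)
            lon[d] = distal[1] + rng.normal(0.0, 0.3)
            regime[d] = "distal"
        elif d < d_ret_end:
            k = d_ret_end - d - 1
            lat[d] = colony[0] + k * (distal[0] - colony[0]) / return_days
            lon[d] = colony[1] + k * (distal[1] - colony[1]) / return_days
            regime[d] = "return"
        else:
            lat[d] = residence[0] + rng.normal(0.0, 0.15)
            lon[d] = residence[1] + rng.normal(0.0, 0.2)
            regime[d] = "residence"

    daily_positions = pd.DataFrame({"date": days, "lat": lat, "lon": lon})
    daily_regime = pd.Series(regime, index=days)

    # burrow-attendance nights: ~11:00–21:00 UTC is local night at 146.5°E
    def night(day_index: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        d0 = days[day_index]
        return d0 + pd.Timedelta(hours=11), d0 + pd.Timedelta(hours=21)

    attendance = [night(d) for d in range(pre_departure_days)]
    last_attendance = attendance[-1][1].normalize()
    first_back = d_ret_end + 3
    res_events = []
    for k in range(n_residence_attendance):
        d = first_back + 12 * k
        if d < total_days:
            res_events.append(night(d))
    attendance += res_events
    moult_start = days[d_out_end + moult_lag_days]
    moult_end = days[d_out_end + moult_lag_days + moult_days - 1]

    return TruthRecord(
        daily_positions=daily_positions,
        daily_regime=daily_regime,
        moult_interval=(moult_start, moult_end),
        attendance_events=attendance,
        last_attendance=last_attendance,
        first_return=res_events[0][0].normalize() if res_events else None,
    )


@dataclass
class BirdYear:
    """One complete simulated bird-year: all data streams plus ground truth."""

    gps_fixes: pd.DataFrame
    gps_truth: TruthRecord
    gls_truth: TruthRecord
    light: pd.DataFrame
    activity: pd.DataFrame
    isotopes: pd.DataFrame


def simulate_bird_year(config: SimConfig | None = None) -> BirdYear:
    """Generate the full bird-year bundle under the default study conditions."""
    if config is None:
        config = SimConfig()
    fixes, gps_truth = simulate_track(config)
    gls_truth = simulate_gls_year(config)
    light = simulate_light(gls_truth.daily_positions, config)
    activity = simulate_activity(gls_truth, config)
    isotopes = simulate_isotopes(
        DEFAULT_ISOTOPE_GROUPS, DEFAULT_ISOTOPE_COV, 15, seed=config.seed + 4
    )
    return BirdYear(
        gps_fixes=fixes,
        gps_truth=gps_truth,
        gls_truth=gls_truth,
        light=light,
        activity=activity,
        isotopes=isotopes,
    )
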