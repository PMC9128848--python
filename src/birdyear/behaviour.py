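"""Movement-state classification by expectation–maximization binary clustering.

Each movement step between consecutive regularized fixes carries a travel
speed (m s⁻¹) and an absolute turning angle (radians, [0, π]).  Speed and
turn are each split into a *low* and a *high* regime by fitting a
two-component univariate Gaussian mixture with EM and placing a delimiter at
the equal-posterior point between the component means.  Combining the two
binary labels yields the four canonical at-sea behavioural states:

====  =========================  ============================
code  speed / turn               interpretation
====  =========================  ============================
LL    low speed, low turn        resting on the water
LH    low speed, high turn       intensive (area-restricted) search
HL    high speed, low turn       travelling / commuting
HH    high speed, high turn      extensive search
====  =========================  ============================

The fit is deterministic: components are initialized by splitting the data at
the median, so rerunning on identical data reproduces the model exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .gps import great_circle_km, initial_bearing_rad

STATES = ("LL", "LH", "HL", "HH")

_SQRT2PI = np.sqrt(2.0 * np.pi)


def step_metrics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-step speed and turning angle from a regularized fix table.

    Step ``i`` spans fixes ``i → i+1``: its speed is the great-circle
    distance over the elapsed time, its turn the absolute difference between
    the bearings of steps ``i−1 → i`` and ``i → i+1`` wrapped to [0, π].
    The first step and any step touching a missing fix have NaN turn/speed
    and are left unlabelled downstream.  Each step carries the mid-time and
    mid-position of its two fixes.
    """
    if len(fixes) < 3:
        return pd.DataFrame(
            columns=["bird_id", "time", "lat", "lon", "speed_ms", "turn_rad", "state"]
        )
    df = fixes.reset_index(drop=True)
    t = pd.to_datetime(df["time"])
    if t.dt.tz is None:
        t = t.dt.tz_localize("UTC")
    tt = t.to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    dt = np.diff(tt)
    dist_km = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = np.where(dt > 0, dist_km * 1000.0 / dt, np.nan)
    bearing = initial_bearing_rad(lat[:-1], lon[:-1], lat[1:], lon[1:])
    turn = np.full(len(speed), np.nan)
    db = np.abs(np.diff(bearing))
    turn[1:] = np.minimum(db, 2.0 * np.pi - db)
    mid_t = pd.to_datetime((tt[:-1] + dt / 2.0) * 1e9).tz_localize("UTC")
    return pd.DataFrame(
        {
            "bird_id": df["bird_id"].iloc[0],
            "time": mid_t,
            "lat": (lat[:-1] + lat[1:]) / 2.0,
            "lon": (lon[:-1] + lon[1:]) / 2.0,
            "speed_ms": speed,
            "turn_rad": turn,
            "state": "unlabelled",
        }
    )


@dataclass
class BinarySplit:
    """Two-component Gaussian mixture fit for one variable, with delimiter."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    delimiter: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    degenerate: bool = False


@dataclass
class EmbcModel:
    """Fitted binary-clustering model: one :class:`BinarySplit` per variable."""

    speed: BinarySplit
    turn: BinarySplit

    def to_dict(self) -> dict:
        out = {}
        for name in ("speed", "turn"):
            s: BinarySplit = getattr(self, name)
            out[name] = {
                "weights": list(s.weights),
                "means": list(s.means),
                "sds": list(s.sds),
                "delimiter": s.delimiter,
                "n_iterations": s.n_iterations,
                "degenerate": s.degenerate,
            }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "EmbcModel":
        splits = {}
        for name in ("speed", "turn"):
            v = d[name]
            splits[name] = BinarySplit(
                weights=tuple(v["weights"]),
                means=tuple(v["means"]),
                sds=tuple(v["sds"]),
                delimiter=v["delimiter"],
                n_iterations=v.get("n_iterations", 0),
                degenerate=v.get("degenerate", False),
            )
        return cls(**splits)


def _normal_pdf(x, mu, sd):
    z = (x - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * _SQRT2PI)


def _equal_posterior_point(w, mu, sd) -> float:
    """Point between the two component means with equal posterior probability.

    Solves w1 N(x; μ1, σ1) = w2 N(x; μ2, σ2), a quadratic in x; the root
    lying strictly between the means is the delimiter.  Falls back to the
    midpoint when no interior root exists (e.g. equal variances with extreme
    weights).
    """
    (w1, w2), (m1, m2), (s1, s2) = w, mu, sd
    lo, hi = min(m1, m2), max(m1, m2)
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * np.log((w1 * s2) / (w2 * s1))
    if abs(a) < 1e-300:
        if abs(b) < 1e-300:
            return (lo + hi) / 2.0
        roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            return (lo + hi) / 2.0
        sq = np.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    interior = [r for r in roots if lo < r < hi]
    if interior:
        return float(interior[0])
    return (lo + hi) / 2.0


def _em_binary(
    x: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> BinarySplit:
    """Deterministic 2-component univariate Gaussian-mixture EM.

    Initialization splits the sorted data at the median; convergence when
    the log-likelihood gain drops below ``tol`` (or ``max_iter``).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        raise ValueError("no finite observations to cluster")
    if np.ptp(x) == 0.0 or np.std(x) == 0.0:
        warnings.warn("degenerate variable (zero variance); delimiter set to its value")
        v = float(x[0])
        return BinarySplit(
            weights=(0.5, 0.5), means=(v, v), sds=(0.0, 0.0), delimiter=v, degenerate=True
        )
    med = np.median(x)
    lo = x[x <= med]
    hi = x[x > med]
    if len(hi) == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    sd_floor = max(np.std(x) * 1e-4, 1e-12)
    sd = np.maximum([lo.std(), hi.std()], sd_floor)
    w = np.array([len(lo), len(hi)], dtype=float) / n
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        p = np.stack([w[k] * _normal_pdf(x, mu[k], sd[k]) for k in (0, 1)])
        tot = p.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.sum(np.log(tot)))
        trace.append(ll)
        r = p / tot
        # M step
        nk = np.maximum(r.sum(axis=1), 1e-12)
        mu = (r * x).sum(axis=1) / nk
        sd = np.sqrt(np.maximum((r * (x - mu[:, None]) ** 2).sum(axis=1) / nk, 0.0))
        sd = np.maximum(sd, sd_floor)
        w = nk / n
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            break
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    delim = _equal_posterior_point(tuple(w), tuple(mu), tuple(sd))
    delim = float(np.clip(delim, x.min(), x.max()))
    return BinarySplit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        delimiter=delim,
        loglik_trace=trace,
        n_iterations=it,
    )


def embc_fit(steps: pd.DataFrame, min_steps: int = 50) -> EmbcModel:
    """Fit the binary-clustering model on a step series.

    Speed and turning angle are clustered independently; each variable
    needs at least ``min_steps`` steps with both metrics finite.
    """
    ok = steps["speed_ms"].notna() & steps["turn_rad"].notna()
    if ok.sum() < min_steps:
        raise ValueError(
            f"need at least {min_steps} labelled-eligible steps, got {int(ok.sum())}"
        )
    return EmbcModel(
        speed=_em_binary(steps.loc[ok, "speed_ms"].to_numpy(float)),
        turn=_em_binary(steps.loc[ok, "turn_rad"].to_numpy(float)),
    )


def embc_classify(steps: pd.DataFrame, model: EmbcModel) -> pd.DataFrame:
    """Label each step LL/LH/HL/HH by its side of the two delimiters.

    First letter = speed regime, second = turn regime; steps with a missing
    metric stay ``unlabelled``.
    """
    out = steps.copy()
    speed = out["speed_ms"].to_numpy(float)
    turn = out["turn_rad"].to_numpy(float)
    ok = np.isfinite(speed) & np.isfinite(turn)
    s_hi = speed > model.speed.delimiter
    t_hi = turn > model.turn.delimiter
    labels = np.where(s_hi, "H", "L").astype(object) + np.where(t_hi, "H", "L")
    out["state"] = np.where(ok, labels, "unlabelled")
    return out


def behaviour_proportions(
    steps: pd.DataFrame, by: str | list[str] = "trip_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time-weighted behaviour percentages per trip, and pooled mean ± sd.

    ``steps`` must carry a grouping column (default ``trip_id``) and a
    ``state`` column; steps are weighted by their duration when a ``dt_s``
    column is present, otherwise equally.  Trips with no labelled steps are
    excluded.

    Returns ``(per_trip, pooled)``: per-trip percentage table (one column per
    state, rows sum to 100 over labelled states) and a two-row mean/sd
    summary across trips.
    """
    df = steps[steps["state"].isin(STATES)].copy()
    if "dt_s" not in df.columns:
        df["dt_s"] = 1.0
    per = (
        df.groupby(by)
        .apply(
            lambda g: pd.Series(
                {
                    s: 100.0 * g.loc[g["state"] == s, "dt_s"].sum() / g["dt_s"].sum()
                    for s in STATES
                }
            ),
            include_groups=False,
        )
        .astype(float)
    )
    pooled = pd.DataFrame({"mean": per.mean(axis=0), "sd": per.std(axis=0, ddof=1)}).T
    return per, pooled


def diel_profile(
    steps: pd.DataFrame, night_threshold: float = -6.0
) -> pd.DataFrame:
    """Hourly behaviour proportions in local solar time, with a night flag.

    Each labelled step is binned by its local solar hour (UTC hour +
    longitude/15°); a bin is "night" when the mean solar elevation of its
    steps is below ``night_threshold`` (default −6°, civil twilight).
    """
    df = steps[steps["state"].isin(STATES) & steps["lat"].notna()].copy()
    if len(df) == 0:
        return pd.DataFrame(columns=["hour", *STATES, "night"])
    t = pd.to_datetime(df["time"])
    utc_hours = t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0
    solar_hour = np.mod(utc_hours + df["lon"].to_numpy(float) / 15.0, 24.0)
    df["hour"] = solar_hour.astype(int)
    elev = np.array(
        [
            solar.solar_elevation(ti, la, lo)
            for ti, la, lo in zip(t, df["lat"], df["lon"])
        ]
    )
    df["elev"] = elev
    rows = []
    for hour, g in df.groupby("hour"):
        counts = g["state"].value_counts()
        total = counts.sum()
        row = {"hour": hour}
        for s in STATES:
            row[s] = counts.get(s, 0) / total
        row["night"] = bool(g["elev"].mean() < night_threshold)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("hour").reset_index(drop=True)
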