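"""Stable-isotope δ notation and isotopic-niche geometry.

δ¹³C and δ¹⁵N (‰, relative to Vienna Pee Dee Belemnite and atmospheric N₂)
proxy foraging habitat and trophic level.  Whole blood integrates diet over
the preceding two–four weeks (breeding season); body feathers record diet at
synthesis (non-breeding).  Comparing the two tissues requires additive
tissue-correction offsets applied to the feather values.

Niche geometry in the δ¹³C–δ¹⁵N plane uses two standard summaries: the
coverage ellipse of the bivariate-normal fit (default 40% coverage) and the
100% total convex hull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.stats import chi2


def delta_value(r_sample, r_standard):
    """δ notation: δX = (R_sample / R_standard − 1) × 1000, in ‰."""
    rs = np.asarray(r_sample, dtype=float)
    rt = np.asarray(r_standard, dtype=float)
    if np.any(rs <= 0) or np.any(rt <= 0):
        raise ValueError("isotope ratios must be positive")
    d = (rs / rt - 1.0) * 1000.0
    if np.isscalar(r_sample) and np.isscalar(r_standard):
        return float(d)
    return d


def ratio_from_delta(delta, r_standard):
    """Inverse of :func:`delta_value`: R_sample from a δ value in ‰."""
    return (np.asarray(delta, dtype=float) / 1000.0 + 1.0) * np.asarray(
        r_standard, dtype=float
    )


def apply_feather_correction(
    samples: pd.DataFrame, d13c_offset: float, d15n_offset: float
) -> pd.DataFrame:
    """Additive tissue correction of feather samples onto the blood scale.

    The offsets are taken from the tissue-comparison literature and must be
    supplied by the caller; outputs record them so the correction is
    auditable and cannot be applied twice (guarded by the ``corrected``
    flag).  Blood rows pass through unchanged.
    """
    df = samples.copy()
    if "corrected" not in df.columns:
        df["corrected"] = False
    feather = df["tissue"] == "feather"
    if bool((df.loc[feather, "corrected"]).any()):
        raise ValueError("feather correction already applied (corrected flag set)")
    df.loc[feather, "d13C"] = df.loc[feather, "d13C"] + d13c_offset
    df.loc[feather, "d15N"] = df.loc[feather, "d15N"] + d15n_offset
    df.loc[feather, "corrected"] = True
    df.attrs["feather_correction"] = (d13c_offset, d15n_offset)
    return df


@dataclass
class NicheEllipse:
    """Coverage ellipse of a bivariate-normal niche in (δ¹³C, δ¹⁵N)."""

    centroid: tuple[float, float]
    covariance: np.ndarray
    coverage: float
    semi_axes: tuple[float, float]
    area: float  # ‰²

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: Mahalanobis distance² ≤ the coverage quantile."""
        q = chi2.ppf(self.coverage, df=2)
        diff = np.asarray(points, dtype=float) - np.asarray(self.centroid)
        inv = np.linalg.inv(self.covariance)
        m2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        return m2 <= q

    def boundary(self, n: int = 181) -> np.ndarray:
        """(n, 2) points on the ellipse boundary, for plotting/export."""
        q = chi2.ppf(self.coverage, df=2)
        vals, vecs = np.linalg.eigh(self.covariance)
        t = np.linspace(0.0, 2.0 * np.pi, n)
        circ = np.stack([np.cos(t), np.sin(t)], axis=1)
        return np.asarray(self.centroid) + circ * np.sqrt(q * vals) @ vecs.T


def niche_ellipse(samples: pd.DataFrame, coverage: float = 0.40) -> NicheEllipse:
    """Coverage ellipse of the sample cloud.

    Centroid = sample mean, shape = sample covariance; the boundary is the
    Mahalanobis contour at the chi-square(2 df) quantile of ``coverage``,
    with area π·q·√det Σ.
    """
    x = samples[["d13C", "d15N"]].dropna().to_numpy(float)
    if len(x) < 3:
        raise ValueError("niche ellipse needs at least 3 samples")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must be in (0, 1)")
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 1e-300:
        raise ValueError("singular covariance: d13C and d15N are collinear")
    q = chi2.ppf(coverage, df=2)
    vals = np.linalg.eigvalsh(cov)
    return NicheEllipse(
        centroid=(float(mu[0]), float(mu[1])),
        covariance=cov,
        coverage=coverage,
        semi_axes=(float(np.sqrt(q * vals[1])), float(np.sqrt(q * vals[0]))),
        area=float(np.pi * q * np.sqrt(det)),
    )


@dataclass
class NicheHull:
    """Convex hull of the sample cloud in (δ¹³C, δ¹⁵N)."""

    vertices: np.ndarray  # (k, 2), counter-clockwise
    area: float  # ‰²
    degenerate: bool = False


def niche_hull(samples: pd.DataFrame) -> NicheHull:
    """100% total convex hull of the δ¹³C–δ¹⁵N points (shoelace area)."""
    x = samples[["d13C", "d15N"]].dropna().to_numpy(float)
    if len(x) < 3:
        raise ValueError("convex hull needs at least 3 samples")
    try:
        hull = ConvexHull(x)
    except Exception:
        # collinear points: zero-area degenerate polygon
        order = np.lexsort((x[:, 1], x[:, 0]))
        return NicheHull(vertices=x[order], area=0.0, degenerate=True)
    return NicheHull(vertices=x[hull.vertices], area=float(hull.volume))
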