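"""Gridded kernel utilization distributions, contours and overlap.

A utilization distribution (UD) is a probability surface of space use,
estimated here with an isotropic bivariate Gaussian kernel on a regular
lat/lon grid and normalized to unit mass.  Conventions follow standard
seabird-tracking practice: GPS tracks use a smoothing parameter (kernel sd)
of h = 0.2° on a 0.1° grid; geolocation tracks h = 1.8° (a search radius of
roughly 200 km at these latitudes) on a 1° grid.  The 50% contour is the
core foraging area, the 95% contour the home range, and similarity between
two UDs is Bhattacharyya's affinity BA = Σ√(pᵢqᵢ) ∈ [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: km per degree of latitude on the mean-radius sphere.
KM_PER_DEG = 111.19493


@dataclass
class GridUD:
    """A normalized utilization distribution on a regular lat/lon grid.

    ``density`` is a (n_lat, n_lon) array of cell *mass* (not density per
    area): it sums to 1.  ``lat0``/``lon0`` are the centre coordinates of
    the [0, 0] cell; row i has latitude ``lat0 + i*cell``.
    """

    lat0: float
    lon0: float
    cell: float
    density: np.ndarray = field(repr=False)
    h: float = np.nan
    source: str = "gps"

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + self.cell * np.arange(self.density.shape[0])

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + self.cell * np.arange(self.density.shape[1])

    def grid_spec(self) -> tuple:
        return (
            round(self.lat0, 9),
            round(self.lon0, 9),
            round(self.cell, 9),
            self.density.shape,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form ``lat, lon, mass`` table (all cells)."""
        lat, lon = np.meshgrid(self.lat_centers, self.lon_centers, indexing="ij")
        return pd.DataFrame(
            {"lat": lat.ravel(), "lon": lon.ravel(), "mass": self.density.ravel()}
        )


def kernel_ud(
    points: pd.DataFrame,
    h_degrees: float,
    cell_degrees: float,
    extent: tuple[float, float, float, float] | None = None,
    source: str = "gps",
) -> GridUD:
    """Gaussian-kernel utilization distribution of a point set.

    ``points`` needs ``lat``/``lon`` columns (NaN rows ignored).  An
    isotropic bivariate Gaussian kernel of standard deviation ``h_degrees``
    is evaluated at cell centres and summed over points; the grid is
    normalized to unit mass.  ``extent`` is (lat_min, lat_max, lon_min,
    lon_max); when omitted, the point bounding box padded by 3h.
    """
    pts = points.dropna(subset=["lat", "lon"])
    if len(pts) == 0:
        raise ValueError("kernel_ud needs at least one point")
    if h_degrees <= 0 or cell_degrees <= 0:
        raise ValueError("bandwidth and cell size must be positive")
    lat = pts["lat"].to_numpy(float)
    lon = pts["lon"].to_numpy(float)
    if extent is None:
        pad = 3.0 * h_degrees
        extent = (lat.min() - pad, lat.max() + pad, lon.min() - pad, lon.max() + pad)
    lat_min, lat_max, lon_min, lon_max = extent
    lat_c = np.arange(lat_min + cell_degrees / 2.0, lat_max, cell_degrees)
    lon_c = np.arange(lon_min + cell_degrees / 2.0, lon_max, cell_degrees)
    # separable kernel: density = A @ B with A (nlat × npts), B (npts × nlon)
    a = np.exp(-0.5 * ((lat_c[:, None] - lat[None, :]) / h_degrees) ** 2)
    b = np.exp(-0.5 * ((lon[:, None] - lon_c[None, :]) / h_degrees) ** 2)
    dens = a @ b
    total = dens.sum()
    if total <= 0:
        raise ValueError("all kernel mass fell outside the grid extent")
    return GridUD(
        lat0=float(lat_c[0]),
        lon0=float(lon_c[0]),
        cell=float(cell_degrees),
        density=dens / total,
        h=float(h_degrees),
        source=source,
    )


@dataclass
class UdContour:
    """Cells of the smallest region holding ``level`` of the UD mass."""

    level: float
    mask: np.ndarray = field(repr=False)
    area_km2: float = np.nan


def ud_contours(ud: GridUD, levels: tuple[float, ...] = (0.5, 0.95)) -> list[UdContour]:
    """Volume contours: highest-density cells whose cumulative mass ≥ level.

    Cell areas use a cos(latitude) correction.  Contours nest: the 50% mask
    is a subset of the 95% mask by construction.
    """
    flat = ud.density.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    lat_grid = np.repeat(ud.lat_centers, ud.density.shape[1])
    cell_area = (KM_PER_DEG * ud.cell) ** 2 * np.cos(np.radians(lat_grid))
    out = []
    for level in levels:
        k = int(np.searchsorted(csum, level)) + 1
        k = min(k, len(flat))
        mask_flat = np.zeros(len(flat), dtype=bool)
        mask_flat[order[:k]] = True
        area = float(cell_area[mask_flat].sum())
        out.append(
            UdContour(level=level, mask=mask_flat.reshape(ud.density.shape), area_km2=area)
        )
    return out


def ba_overlap(ud1: GridUD, ud2: GridUD) -> float:
    """Bhattacharyya's affinity between two UDs on the identical grid.

    BA = Σ√(pᵢqᵢ): 0 for disjoint distributions, 1 for identical ones.
    Grids must match exactly; re-grid first with :func:`regrid`.
    """
    if ud1.grid_spec() != ud2.grid_spec():
        raise ValueError(
            f"UD grids differ: {ud1.grid_spec()} vs {ud2.grid_spec()}; "
            "regrid to a common grid first"
        )
    return float(np.sum(np.sqrt(ud1.density * ud2.density)))


def regrid(ud: GridUD, target_cell: float) -> GridUD:
    """Mass-conserving resample to a coarser or finer aligned grid.

    The target cell size must be an integer multiple (aggregation: blocks of
    cells summed) or divisor (refinement: mass split equally) of the source
    cell size.
    """
    ratio = target_cell / ud.cell
    if abs(ratio - round(ratio)) < 1e-9 and round(ratio) >= 1:
        f = int(round(ratio))
        if f == 1:
            return GridUD(ud.lat0, ud.lon0, ud.cell, ud.density.copy(), ud.h, ud.source)
        nlat, nlon = ud.density.shape
        pl, pn = (-nlat) % f, (-nlon) % f
        d = np.pad(ud.density, ((0, pl), (0, pn)))
        coarse = d.reshape(d.shape[0] // f, f, d.shape[1] // f, f).sum(axis=(1, 3))
        # cell centres shift to the centre of each f×f block
        off = ud.cell * (f - 1) / 2.0
        return GridUD(
            ud.lat0 + off, ud.lon0 + off, target_cell, coarse, ud.h, ud.source
        )
    inv = ud.cell / target_cell
    if abs(inv - round(inv)) < 1e-9 and round(inv) >= 1:
        f = int(round(inv))
        fine = np.repeat(np.repeat(ud.density, f, axis=0), f, axis=1) / (f * f)
        off = ud.cell / 2.0 - target_cell / 2.0
        return GridUD(
            ud.lat0 - off, ud.lon0 - off, target_cell, fine, ud.h, ud.source
        )
    raise ValueError(
        f"target cell {target_cell} is not an integer multiple or divisor of "
        f"source cell {ud.cell}"
    )


def contours_to_geojson(ud: GridUD, contours: list[UdContour]) -> str:
    """GeoJSON FeatureCollection of contour masks as per-cell polygons."""
    half = ud.cell / 2.0
    feats = []
    for c in contours:
        polys = []
        idx = np.argwhere(c.mask)
        for i, j in idx:
            la = ud.lat0 + i * ud.cell
            lo = ud.lon0 + j * ud.cell
            ring = [
                [lo - half, la - half],
                [lo + half, la - half],
                [lo + half, la + half],
                [lo - half, la + half],
                [lo - half, la - half],
            ]
            polys.append([ring])
        feats.append(
            {
                "type": "Feature",
                "properties": {"level": c.level, "area_km2": c.area_km2},
                "geometry": {"type": "MultiPolygon", "coordinates": polys},
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": feats})
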