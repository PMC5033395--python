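"""Terrain derivatives, distance transforms, hulls and density isopleths.

These are the geometric primitives behind the habitat layers: the terrain
ruggedness index (TRI) of Riley et al. — the square root of the summed
squared elevation differences between a cell and its eight neighbours —
Euclidean distance-to-feature grids for the two road classes, the 100%
minimum convex polygon delimiting availability, and kernel-density
isopleths used to delineate residency core polygons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from scipy.stats import gaussian_kde
from shapely.geometry import MultiPoint, Polygon, box
from shapely.geometry.base import BaseGeometry

from .raster import LandscapeStack, Raster, VectorLayer

__all__ = [
    "terrain_ruggedness",
    "slope_aspect",
    "distance_to_features",
    "minimum_convex_polygon",
    "density_isopleth",
    "extract_covariates",
]

_NEIGHBOUR_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def terrain_ruggedness(dem: Raster) -> Raster:
    """Riley's TRI: sqrt of summed squared differences to the 8 neighbours.

    Edge cells use only their existing neighbours; a neighbour that is
    nodata is likewise skipped.  A flat surface yields 0 everywhere.
    """
    mask = dem.mask()
    if not mask.any():
        raise ValueError("all-nodata DEM: no terrain to summarize")
    z = np.where(mask, dem.values, np.nan)
    ssq = np.zeros_like(z)
    for dr, dc in _NEIGHBOUR_SHIFTS:
        shifted = np.full_like(z, np.nan)
        src = z[
            max(dr, 0) : z.shape[0] + min(dr, 0),
            max(dc, 0) : z.shape[1] + min(dc, 0),
        ]
        shifted[
            max(-dr, 0) : z.shape[0] + min(-dr, 0),
            max(-dc, 0) : z.shape[1] + min(-dc, 0),
        ] = src
        diff = z - shifted
        ssq += np.where(np.isnan(diff), 0.0, diff**2)
    tri = np.sqrt(ssq)
    tri[~mask] = np.nan
    return dem.like(tri)


def slope_aspect(dem: Raster) -> tuple[Raster, Raster]:
    """Slope (degrees) and aspect (degrees clockwise from north) by central
    differences; aspect of flat cells is 0 by convention."""
    mask = dem.mask()
    z = np.where(mask, dem.values, np.nan)
    dz_dy, dz_dx = np.gradient(z, dem.cell_size)
    dz_dy = -dz_dy  # rows increase southwards
    slope = np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))
    aspect = np.degrees(np.arctan2(dz_dx, dz_dy)) % 360.0
    aspect[np.hypot(dz_dx, dz_dy) == 0] = 0.0
    slope[~mask] = np.nan
    aspect[~mask] = np.nan
    return dem.like(slope), dem.like(aspect)


def distance_to_features(features: VectorLayer, grid: Raster) -> Raster:
    """Euclidean distance (m) from every cell centre to the nearest feature."""
    if len(features) == 0:
        raise ValueError("empty feature layer")
    union = features.union()
    xs, ys = grid.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    dist = shapely.distance(pts, union).reshape(grid.shape)
    return grid.like(dist)


def minimum_convex_polygon(points) -> Polygon:
    """100% minimum convex polygon (convex hull) around a point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a convex polygon")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("degenerate geometry: points are collinear")
    return hull


def density_isopleth(points, level: float, grid: Raster) -> list[Polygon]:
    """Kernel-density isopleth: the smallest set of cells holding >= ``level``
    of the estimated location-density mass, returned as dissolved polygons.

    A Gaussian kernel with Silverman's reference bandwidth is evaluated at
    the grid's cell centres; cells are accumulated in decreasing density
    order until the target mass is reached, so isopleths at increasing
    levels are nested by construction.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 points for a density isopleth")
    kde = gaussian_kde(pts.T, bw_method="silverman")
    xs, ys = grid.cell_centers()
    dens = kde(np.vstack([xs.ravel(), ys.ravel()]))
    order = np.argsort(dens)[::-1]
    mass = np.cumsum(dens[order])
    mass /= mass[-1]
    n_keep = int(np.searchsorted(mass, level) + 1)
    keep = np.zeros(dens.size, dtype=bool)
    keep[order[:n_keep]] = True
    keep = keep.reshape(grid.shape)
    return cells_to_polygons(keep, grid)


def cells_to_polygons(mask: np.ndarray, grid: Raster) -> list[Polygon]:
    """Dissolve a boolean cell mask into polygons (one per dissolved blob)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    x0, y0 = grid.origin
    cs = grid.cell_size
    boxes = shapely.box(
        x0 + cols * cs, y0 - (rows + 1) * cs, x0 + (cols + 1) * cs, y0 - rows * cs
    )
    # cells form a non-overlapping coverage; coverage union is much faster
    # than a general union for large masks
    merged = shapely.coverage_union_all(boxes)
    if merged.geom_type == "GeometryCollection":
        merged = shapely.union_all(boxes)
    if isinstance(merged, Polygon):
        return [merged]
    return list(merged.geoms)


def extract_covariates(points, stack: LandscapeStack) -> pd.DataFrame:
    """Sample every stack layer at each point.

    Returns one row per point with one column per layer plus a boolean
    ``missing`` flag set when any layer is nodata at that point.  Points
    outside the grid extent raise, naming the first offending point; the
    extent is inclusive of its boundary.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    grid = stack.grid
    row, col, inside = grid.index_of(pts[:, 0], pts[:, 1])
    if not inside.all():
        bad = pts[~inside][0]
        raise ValueError(f"point ({bad[0]:.1f}, {bad[1]:.1f}) is outside the landscape extent")
    out = {}
    missing = np.zeros(pts.shape[0], dtype=bool)
    for name, raster in stack.layers.items():
        vals = raster.values[row, col]
        ok = raster.mask()[row, col]
        missing |= ~ok
        out[name] = np.where(ok, vals, np.nan)
    table = pd.DataFrame(out)
    table["missing"] = missing
    return table
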