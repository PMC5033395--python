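"""Friction surfaces and normalized least-cost corridors.

The fitted step-selection model is mapped over the landscape to a relative
probability surface (exp(b.x), rescaled to [0, 1]); friction is its
complement, so cells elk select strongly are cheap to cross.  A no-roads
counterfactual surface is produced by holding both road-distance layers at
their caps before scoring.  Corridors between residency core areas follow
the Linkage-Mapper construction: per core pair, cost-weighted distance
(CWD) rasters are summed and normalized by the least-cost path distance,

    NLCC_AB = CWD_A + CWD_B - LCD_AB,

which is zero exactly along the least-cost path; pairwise corridors are
mosaicked by cellwise minimum and cropped at a maximum CWD for mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from shapely.geometry import Polygon

from .geo import cells_to_polygons, extract_covariates
from .models import FittedModel
from .raster import LandscapeStack, Raster
from .simulate import ROAD_CAPS

log = logging.getLogger(__name__)

__all__ = [
    "FrictionSurface",
    "CorridorSet",
    "prediction_surface",
    "friction_from_surface",
    "no_roads_surface",
    "extract_cores",
    "pair_cores",
    "cost_weighted_distance",
    "normalized_corridor",
    "mosaic_minimum",
    "crop_corridors",
    "build_corridors",
]

EPSILON_DEFAULT = 1e-6


@dataclass
class FrictionSurface:
    """Per-cell movement resistance in [epsilon, 1]."""

    raster: Raster
    scenario: str = "actual"  # "actual" | "no_roads"
    season: str = "spring"  # "spring" | "autumn"
    epsilon: float = EPSILON_DEFAULT


@dataclass
class CorridorSet:
    """Cores, pairs and per-pair corridor rasters plus the mosaics.

    ``mosaic`` is the cellwise minimum of normalized corridors (NLCC, zero
    along least-cost paths); ``cwd_mosaic`` is the cellwise minimum of the
    raw CWD sums (NLCC + LCD per pair), the total cost of the cheapest
    core-to-core route through each cell.  Cropping the corridor map at a
    maximum CWD applies the cutoff to ``cwd_mosaic``: a core pair whose
    least-cost route exceeds the budget drops out entirely, which is how a
    road barrier can close a crossing rather than merely narrow it.
    """

    cores: list[Polygon]
    pairs: list[tuple[int, int, float]]  # (i, j, edge-to-edge distance m)
    cwd: dict  # (i, j) -> (cwd_a, cwd_b)
    lcd: dict  # (i, j) -> least-cost path distance
    nlcc: dict  # (i, j) -> Raster
    mosaic: Raster | None
    cwd_mosaic: Raster | None
    cwd_cutoff: float

    def cropped(self) -> Raster:
        """NLCC mosaic restricted to cells within the CWD budget."""
        if self.mosaic is None:
            raise ValueError("no corridors were built")
        vals = self.mosaic.values.copy()
        vals[~(self.cwd_mosaic.values <= self.cwd_cutoff)] = np.nan
        return self.mosaic.like(vals)


def _stack_rows(stack: LandscapeStack, model: FittedModel, override: dict | None = None):
    names = [n for n in model.spec.continuous] + [n for n in model.spec.categorical]
    missing = [n for n in names if n not in stack.layers]
    if missing:
        raise KeyError(f"model term(s) with no landscape layer: {missing}")
    rows = {}
    for n in names:
        v = stack[n].values.ravel().astype(float)
        if override and n in override:
            v = np.full_like(v, override[n])
        rows[n] = v
    return pd.DataFrame(rows)


def prediction_surface(model: FittedModel, stack: LandscapeStack) -> Raster:
    """Relative selection probability per cell: exp(b.x)/max, in [0, 1]."""
    rows = _stack_rows(stack, model)
    lin = model.linear_predictor(rows, include_intercept=False).reshape(stack.grid.shape)
    valid = stack.valid_mask()
    lin = np.where(valid, lin, np.nan)
    w = np.exp(lin - np.nanmax(lin))
    return stack.grid.like(w)


def no_roads_surface(model: FittedModel, stack: LandscapeStack, caps: dict | None = None) -> Raster:
    """Counterfactual surface with road distances held at their caps.

    Both road-distance layers are set everywhere to their cap values (2 km
    highways, 1 km gravel) before scoring — every cell is scored as if it
    were far from any road — then the surface is renormalized by its own
    maximum.  Removing the road terms instead would misspecify the model.
    """
    caps = caps or ROAD_CAPS
    override = {n: c for n, c in caps.items() if n in model.spec.continuous}
    rows = _stack_rows(stack, model, override=override)
    lin = model.linear_predictor(rows, include_intercept=False).reshape(stack.grid.shape)
    valid = stack.valid_mask()
    lin = np.where(valid, lin, np.nan)
    w = np.exp(lin - np.nanmax(lin))
    return stack.grid.like(w)


def friction_from_surface(
    surface: Raster, epsilon: float = EPSILON_DEFAULT, scenario: str = "actual", season: str = "spring"
) -> FrictionSurface:
    """Friction = max(1 - relative probability, epsilon)."""
    vals = surface.values
    fr = np.maximum(1.0 - vals, epsilon)
    fr[~surface.mask()] = np.nan
    return FrictionSurface(surface.like(fr), scenario=scenario, season=season, epsilon=epsilon)


def extract_cores(
    rsf_raster: Raster, quantile: float = 0.75, min_cells: int = 1
) -> list[Polygon]:
    """Residency core areas: cells scoring at or above the given quantile of
    valid-cell scores, dissolved into 8-connected components."""
    mask = rsf_raster.mask()
    vals = rsf_raster.values
    v = vals[mask]
    if v.size < 4:
        raise ValueError("raster too small to extract cores")
    if np.ptp(v) == 0:
        warnings.warn("degenerate score raster (all values equal); every valid cell qualifies")
        hi = mask
    else:
        thr = np.quantile(v, quantile)
        hi = mask & (vals >= thr)
    labels, n = cc_label(hi, structure=np.ones((3, 3)))
    polys = []
    for i in range(1, n + 1):
        m = labels == i
        if m.sum() >= min_cells:
            polys.extend(cells_to_polygons(m, rsf_raster))
    return polys


def pair_cores(cores_from, cores_to, max_km: float = 80.0) -> list[tuple[int, int, float]]:
    """All (i, j) core pairs whose edge-to-edge distance is <= max_km (inclusive)."""
    if not cores_from or not cores_to:
        raise ValueError("both core sets must be non-empty")
    pairs = []
    for i, a in enumerate(cores_from):
        for j, b in enumerate(cores_to):
            d = a.distance(b)
            if d <= max_km * 1000.0:
                pairs.append((i, j, float(d)))
    return pairs


def _move_graph(friction: FrictionSurface):
    """Sparse 8-connected move graph: edge cost = mean cell friction x
    centre-to-centre distance (the Linkage Mapper / ArcGIS convention)."""
    r = friction.raster
    f = r.values
    valid = r.mask()
    nrow, ncol = f.shape
    idx = np.arange(f.size).reshape(f.shape)
    rows, cols, costs = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, -dr), nrow - max(0, dr)
        c0, c1 = max(0, -dc), ncol - max(0, dc)
        a = idx[r0:r1, c0:c1].ravel()
        b = idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        ok = valid.ravel()[a] & valid.ravel()[b]
        a, b = a[ok], b[ok]
        dist = r.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        w = 0.5 * (f.ravel()[a] + f.ravel()[b]) * dist
        rows.append(a)
        cols.append(b)
        costs.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    costs = np.concatenate(costs)
    n = f.size
    return coo_matrix(
        (np.concatenate([costs, costs]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()


def _source_cells(friction: FrictionSurface, source) -> np.ndarray:
    r = friction.raster
    valid = r.mask()
    if isinstance(source, Polygon) or hasattr(source, "geom_type"):
        xs, ys = r.cell_centers()
        import shapely

        inside = shapely.contains_xy(source, xs.ravel(), ys.ravel()).reshape(r.shape)
        if not inside.any():
            # small polygon between cell centres: take the cell holding the centroid
            row, col, ok = r.index_of(source.centroid.x, source.centroid.y)
            if ok:
                inside[row, col] = True
        cells = np.flatnonzero(inside.ravel() & valid.ravel())
    else:
        cells = np.asarray(source, dtype=int).ravel()
        cells = cells[valid.ravel()[cells]]
    if cells.size == 0:
        raise ValueError("source does not intersect any valid cell")
    return cells


def cost_weighted_distance(friction: FrictionSurface, source) -> Raster:
    """Minimal accumulated cost from the source to every cell.

    Moves are 8-connected; the cost of a move is the mean of the two cell
    frictions times the centre-to-centre distance (cell_size, or
    cell_size*sqrt(2) diagonally).  Source cells are 0.
    """
    cells = _source_cells(friction, source)
    graph = _move_graph(friction)
    d = dijkstra(graph, directed=False, indices=cells, min_only=True)
    out = d.reshape(friction.raster.shape)
    out[~friction.raster.mask()] = np.nan
    return friction.raster.like(out)


def normalized_corridor(cwd_a: Raster, cwd_b: Raster) -> tuple[float, Raster]:
    """LCD and NLCC per the corridor normalization identity.

    LCD is the minimum over cells of CWD_A + CWD_B (the least-cost path
    distance between the cores); NLCC = CWD_A + CWD_B - LCD is zero exactly
    on least-cost-path cells and positive elsewhere.
    """
    if not cwd_a.same_grid(cwd_b):
        raise ValueError("CWD rasters must share one grid")
    total = cwd_a.values + cwd_b.values
    finite = np.isfinite(total)
    if not finite.any():
        raise ValueError("no cell reachable from both cores: corridors undefined")
    lcd = float(np.nanmin(total[finite]))
    if not np.isfinite(lcd):
        raise ValueError("no cell reachable from both cores: corridors undefined")
    nlcc = total - lcd
    return lcd, cwd_a.like(nlcc)


def mosaic_minimum(rasters: list[Raster]) -> Raster:
    """Cellwise minimum across corridor rasters, ignoring NaN unless all are."""
    if not rasters:
        raise ValueError("need at least one raster")
    ref = rasters[0]
    for r in rasters[1:]:
        if not r.same_grid(ref):
            raise ValueError("mosaic inputs must share one grid")
    stackv = np.stack([r.values for r in rasters])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmin(stackv, axis=0)
    return ref.like(out)


def crop_corridors(mosaic: Raster, cwd_cutoff: float) -> Raster:
    """Mask mosaic cells above the CWD cutoff (inclusive: the cutoff stays)."""
    if cwd_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    vals = mosaic.values.copy()
    vals[vals > cwd_cutoff] = np.nan
    if not np.isfinite(vals).any():
        warnings.warn("all corridor cells exceed the CWD cutoff")
    return mosaic.like(vals)


def build_corridors(
    friction: FrictionSurface,
    cores_from: list[Polygon],
    cores_to: list[Polygon],
    max_km: float = 80.0,
    cwd_cutoff: float = 200_000.0,
    keep_pair_rasters: bool = False,
) -> CorridorSet:
    """Full corridor construction between two seasonal core sets.

    The mosaic (cellwise minimum over all pairwise normalized corridors) is
    accumulated incrementally; per-pair NLCC rasters are retained only when
    ``keep_pair_rasters`` is set, since a landscape with many core pairs
    would otherwise hold one full raster per pair in memory.
    """
    pairs = pair_cores(cores_from, cores_to, max_km=max_km)
    cwd_cache_a: dict[int, Raster] = {}
    cwd_cache_b: dict[int, Raster] = {}
    cwds, lcds, nlccs = {}, {}, {}
    mosaic_vals = None
    cwd_vals = None
    for i, j, _ in pairs:
        if i not in cwd_cache_a:
            cwd_cache_a[i] = cost_weighted_distance(friction, cores_from[i])
        if j not in cwd_cache_b:
            cwd_cache_b[j] = cost_weighted_distance(friction, cores_to[j])
        try:
            lcd, nlcc = normalized_corridor(cwd_cache_a[i], cwd_cache_b[j])
        except ValueError:
            log.warning("no path between cores %d and %d; pair skipped", i, j)
            continue
        lcds[(i, j)] = lcd
        if keep_pair_rasters:
            cwds[(i, j)] = (cwd_cache_a[i], cwd_cache_b[j])
            nlccs[(i, j)] = nlcc
        if mosaic_vals is None:
            mosaic_vals = nlcc.values
            cwd_vals = nlcc.values + lcd
        else:
            mosaic_vals = np.fmin(mosaic_vals, nlcc.values)
            cwd_vals = np.fmin(cwd_vals, nlcc.values + lcd)
    mosaic = friction.raster.like(mosaic_vals) if mosaic_vals is not None else None
    cwd_mosaic = friction.raster.like(cwd_vals) if cwd_vals is not None else None
    return CorridorSet(
        cores=list(cores_from) + list(cores_to),
        pairs=pairs,
        cwd=cwds,
        lcd=lcds,
        nlcc=nlccs,
        mosaic=mosaic,
        cwd_mosaic=cwd_mosaic,
        cwd_cutoff=cwd_cutoff,
    )
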