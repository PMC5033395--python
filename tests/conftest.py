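"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each quantity with the most naive
correct algorithm (nested loops, heapq Dijkstra, dense sampling) so they
share no code path with the package implementations they check.
"""

import heapq

import numpy as np
import pytest

from movescape.raster import Raster
from movescape.simulate import SimulationConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=42, n_animals=6, n_rows=60, n_cols=60)


@pytest.fixture(scope="session")
def small_stack(small_config):
    return generate_landscape(small_config)


def make_raster(values, cell_size=250.0, nodata=-9999.0):
    values = np.asarray(values, dtype=float)
    return Raster(values, origin=(0.0, values.shape[0] * cell_size), cell_size=cell_size, nodata=nodata)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------
def brute_tri(dem):
    """Riley's TRI by explicit loops over the 8 neighbours."""
    z = np.asarray(dem, dtype=float)
    out = np.zeros_like(z)
    nr, nc = z.shape
    for i in range(nr):
        for j in range(nc):
            ssq = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nr and 0 <= b < nc and np.isfinite(z[a, b]):
                        ssq += (z[i, j] - z[a, b]) ** 2
            out[i, j] = np.sqrt(ssq)
    return out


def brute_hull(points):
    """O(n^3) convex hull: an edge (i, j) is on the hull iff all other
    points lie on one side; returns the set of hull vertices."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if (cross >= -1e-9).all() or (cross <= 1e-9).all():
                on_line = np.abs(cross) <= 1e-9
                # keep only the extreme endpoints of collinear runs
                t = (pts[on_line] - pts[i]) @ d
                if (0 <= t).all() or True:
                    hull.add(tuple(pts[i]))
                    hull.add(tuple(pts[j]))
    return hull


def brute_dijkstra_cwd(friction, cell_size, sources):
    """Heapq Dijkstra over the explicit 8-connected move graph with edge
    cost mean(friction) * distance; independent of scipy.csgraph."""
    f = np.asarray(friction, dtype=float)
    nr, nc = f.shape
    dist = np.full((nr, nc), np.inf)
    heap = []
    for (i, j) in sources:
        dist[i, j] = 0.0
        heapq.heappush(heap, (0.0, i, j))
    while heap:
        d, i, j = heapq.heappop(heap)
        if d > dist[i, j]:
            continue
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if not (0 <= a < nr and 0 <= b < nc):
                    continue
                if not np.isfinite(f[a, b]):
                    continue
                step = cell_size * (np.sqrt(2.0) if di and dj else 1.0)
                nd = d + 0.5 * (f[i, j] + f[a, b]) * step
                if nd < dist[a, b] - 1e-12:
                    dist[a, b] = nd
                    heapq.heappush(heap, (nd, a, b))
    dist[~np.isfinite(f)] = np.nan
    return dist
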