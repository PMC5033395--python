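"""Raster and vector data model.

All coordinates are projected metres.  Rasters follow the GIS convention:
``origin`` is the upper-left corner of the upper-left cell, rows increase
southwards, columns eastwards, and the centre of cell ``(row, col)`` sits at
``(origin_x + (col + 0.5) * cell_size, origin_y - (row + 0.5) * cell_size)``.

Rasters are written to and read from ESRI ASCII grid (``.asc``), a plain-text
interchange format understood by GDAL and QGIS; vectors use GeoJSON via
shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

__all__ = ["Raster", "VectorLayer", "LandscapeStack"]

_NODATA_DEFAULT = -9999.0


@dataclass
class Raster:
    """Single-band grid of values on a regular square-cell lattice.

    Parameters
    ----------
    values
        2-D array.  Cells equal to ``nodata`` (or NaN) are treated as
        missing and excluded from arithmetic.
    origin
        ``(x, y)`` of the *upper-left corner* of the grid in projected metres.
    cell_size
        Cell edge length in metres; must be positive.
    nodata
        Sentinel marking missing cells.
    crs_tag
        Opaque coordinate-system label carried through, never interpreted.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = _NODATA_DEFAULT
    crs_tag: str = "local-metres"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        x0, y0 = self.origin
        return (
            x0,
            y0 - self.n_rows * self.cell_size,
            x0 + self.n_cols * self.cell_size,
            y0,
        )

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a valid value."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask()]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (x, y) of every cell centre, each shaped like ``values``."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def index_of(self, x, y):
        """Row/col of the cell containing each point (inclusive extent).

        Points on the shared edge of two cells belong to the cell with the
        larger row/col index except on the outer boundary, where they are
        pulled back inside so the extent is closed.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        xmin, ymin, xmax, ymax = self.bounds
        inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        col = np.where(inside, np.clip(col, 0, self.n_cols - 1), col)
        row = np.where(inside, np.clip(row, 0, self.n_rows - 1), row)
        return row, col, inside

    def contains(self, x, y) -> np.ndarray:
        _, _, inside = self.index_of(x, y)
        return inside

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster on this grid with different values."""
        return Raster(
            values=np.asarray(values, dtype=float),
            origin=self.origin,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
            crs_tag=self.crs_tag,
        )

    def same_grid(self, other: "Raster", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    # -- I/O -------------------------------------------------------------
    def write_ascii(self, path) -> None:
        vals = np.where(self.mask(), self.values, self.nodata)
        xmin, ymin, _, _ = self.bounds
        header = (
            f"ncols {self.n_cols}\n"
            f"nrows {self.n_rows}\n"
            f"xllcorner {xmin!r}\n"
            f"yllcorner {ymin!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, crs_tag: str = "local-metres") -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        n_rows = int(header["nrows"])
        cell = header["cellsize"]
        origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
        return cls(vals, origin, cell, nodata=header["nodata_value"], crs_tag=crs_tag)


@dataclass
class VectorLayer:
    """Polylines or polygons with per-feature attributes."""

    geometries: list[BaseGeometry]
    attributes: list[dict] = field(default_factory=list)
    crs_tag: str = "local-metres"

    def __post_init__(self) -> None:
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        if len(self.attributes) != len(self.geometries):
            raise ValueError("attributes must match geometries one-to-one")
        for g in self.geometries:
            if g.is_empty:
                raise ValueError("empty geometry in vector layer")

    def __len__(self) -> int:
        return len(self.geometries)

    def union(self) -> BaseGeometry:
        return shapely.union_all(self.geometries)

    def total_length(self) -> float:
        return float(sum(g.length for g in self.geometries))

    def write_geojson(self, path) -> None:
        features = [
            {"type": "Feature", "geometry": geom_mapping(g), "properties": attrs}
            for g, attrs in zip(self.geometries, self.attributes)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def read_geojson(cls, path, crs_tag: str = "local-metres") -> "VectorLayer":
        with open(path) as fh:
            data = json.load(fh)
        geoms = [geom_shape(f["geometry"]) for f in data["features"]]
        attrs = [f.get("properties") or {} for f in data["features"]]
        return cls(geoms, attrs, crs_tag=crs_tag)


class LandscapeStack:
    """Co-registered named rasters sharing one grid, plus road vectors.

    The canonical layer names used across the pipeline are ``dem``,
    ``ruggedness``, ``slope``, ``aspect``, ``canopy``, ``ndvi_winter``,
    ``ndvi_summer``, ``landcover``, ``dist_highway`` and ``dist_gravel``;
    any co-registered layer may be added.
    """

    def __init__(
        self,
        layers: Mapping[str, Raster],
        vectors: Mapping[str, VectorLayer] | None = None,
        categorical: Iterable[str] = ("landcover",),
    ):
        layers = dict(layers)
        if not layers:
            raise ValueError("stack needs at least one layer")
        ref = next(iter(layers.values()))
        for name, r in layers.items():
            if not r.same_grid(ref):
                raise ValueError(f"layer {name!r} is not on the shared grid")
        self.layers: dict[str, Raster] = layers
        self.vectors: dict[str, VectorLayer] = dict(vectors or {})
        self.categorical = set(categorical)

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __setitem__(self, name: str, raster: Raster) -> None:
        if not raster.same_grid(self.grid):
            raise ValueError(f"layer {name!r} is not on the shared grid")
        self.layers[name] = raster

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            m &= r.mask()
        return m

    def write(self, directory) -> None:
        """Write every raster as .asc and every vector as .geojson."""
        import os

        os.makedirs(directory, exist_ok=True)
        for name, r in self.layers.items():
            r.write_ascii(os.path.join(directory, f"{name}.asc"))
        for name, v in self.vectors.items():
            v.write_geojson(os.path.join(directory, f"{name}.geojson"))

    @classmethod
    def read(cls, directory, categorical: Sequence[str] = ("landcover",)) -> "LandscapeStack":
        import glob
        import os

        layers = {
            os.path.splitext(os.path.basename(p))[0]: Raster.read_ascii(p)
            for p in sorted(glob.glob(os.path.join(directory, "*.asc")))
        }
        vectors = {
            os.path.splitext(os.path.basename(p))[0]: VectorLayer.read_geojson(p)
            for p in sorted(glob.glob(os.path.join(directory, "*.geojson")))
        }
        return cls(layers, vectors, categorical=categorical)
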