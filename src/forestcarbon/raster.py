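"""Raster container and GeoTIFF / GeoJSON input-output.

Every gridded layer in the pipeline (canopy height, wood density, biomass,
covariates, masks) is carried as a :class:`RasterGrid`: a 2-D value array with
an affine geotransform and a nodata sentinel.  Conventions, asserted in the
readers: pixel-is-area, row 0 is the northern edge, cells are half-open
intervals ``[x, x + cell)`` east and ``(y - cell, y]`` south.

GeoTIFFs are single-band float32 with nodata -9999, written with the standard
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags so that GIS software
georeferences them correctly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

NODATA = -9999.0

#: Metres per degree of arc in the fixed equal-area working frame.
M_PER_DEG = 111_320.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterAlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """A single-band raster: 2-D values + geotransform + nodata sentinel.

    Parameters
    ----------
    values
        2-D array, row 0 at the northern edge.
    x0, y0
        Map coordinates of the *top-left corner* of pixel (0, 0).
    cell_size
        Square cell edge in metres.
    nodata
        Sentinel for missing cells (default -9999).
    """

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float
    nodata: float = NODATA
    crs: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- basic geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full extent."""
        nrow, ncol = self.shape
        return (
            self.x0,
            self.y0 - nrow * self.cell_size,
            self.x0 + ncol * self.cell_size,
            self.y0,
        )

    def valid_mask(self) -> np.ndarray:
        v = self.values
        with np.errstate(invalid="ignore"):
            return (v != self.nodata) & np.isfinite(v)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates as broadcastable (x of cols, y of rows)."""
        nrow, ncol = self.shape
        xs = self.x0 + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.y0 - (np.arange(nrow) + 0.5) * self.cell_size
        return xs, ys

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full 2-D arrays of pixel-center x and y."""
        xs, ys = self.pixel_centers()
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing map points; may be out of range."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.index_of(x, y)
        return self.values[row, col]

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new raster on this grid carrying ``values``."""
        if values.shape != self.shape:
            raise RasterAlignmentError("replacement values have a different shape")
        return replace(self, values=values)

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) < tol
            and abs(self.y0 - other.y0) < tol
            and abs(self.cell_size - other.cell_size) < tol
        )


def require_aligned(*grids: RasterGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise RasterAlignmentError("rasters do not share a grid")
        if first.crs is not None and g.crs is not None and first.crs != g.crs:
            raise RasterAlignmentError("rasters carry different CRS strings")


# -- GeoTIFF -----------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a single-band float32 GeoTIFF with nodata -9999."""
    values = np.asarray(grid.values, dtype=np.float32)
    values = np.where(np.isfinite(values), values, np.float32(grid.nodata))
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(grid.cell_size), float(grid.cell_size), 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.x0), float(grid.y0), 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, str(float(grid.nodata)), True),
    ]
    desc = json.dumps({"crs": grid.crs}) if grid.crs else None
    tifffile.imwrite(path, values, extratags=extratags, description=desc)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster`."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tiept = page.tags.get(_TAG_TIEPOINT)
        ndtag = page.tags.get(_TAG_GDAL_NODATA)
        desc = page.tags.get("ImageDescription")
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        if scale is None or tiept is None:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells are not supported")
        x0, y0 = float(tiept.value[3]), float(tiept.value[4])
        nodata = float(ndtag.value) if ndtag is not None else NODATA
        crs = None
        if desc is not None:
            try:
                crs = json.loads(desc.value).get("crs")
            except (json.JSONDecodeError, AttributeError):
                crs = None
    return RasterGrid(values=values, x0=x0, y0=y0, cell_size=sx, nodata=nodata, crs=crs)


# -- GeoJSON -----------------------------------------------------------------

def write_geojson(features: list[dict], path: str | Path) -> None:
    """Write a FeatureCollection; each feature is {"geometry": shapely geom,
    "properties": dict}."""
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": f.get("properties", {}),
            }
            for f in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[dict]:
    fc = json.loads(Path(path).read_text())
    return [
        {"geometry": shape(f["geometry"]), "properties": f.get("properties", {})}
        for f in fc["features"]
    ]


# -- block aggregation (shared by MCH aggregation and coarse upscaling) ------

def block_mean(
    grid: RasterGrid, factor: int, min_valid_fraction: float = 0.5
) -> RasterGrid:
    """Aggregate by integer block means of valid cells.

    A coarse cell is nodata when fewer than ``min_valid_fraction`` of its fine
    cells are valid.  Trailing rows/columns that do not fill a block are
    dropped.
    """
    if factor < 1 or int(factor) != factor:
        raise RasterAlignmentError("aggregation factor must be a positive integer")
    factor = int(factor)
    nrow, ncol = grid.shape
    nr, nc = nrow // factor, ncol // factor
    if nr == 0 or nc == 0:
        raise RasterAlignmentError("raster smaller than one aggregation block")
    v = np.asarray(grid.values, dtype=float)[: nr * factor, : nc * factor]
    m = grid.valid_mask()[: nr * factor, : nc * factor]
    v = np.where(m, v, 0.0)
    blocks_sum = v.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    blocks_n = m.reshape(nr, factor, nc, factor).sum(axis=(1, 3))
    frac = blocks_n / float(factor * factor)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = blocks_sum / blocks_n
    out = np.where(frac >= min_valid_fraction, mean, grid.nodata)
    out = np.where(np.isfinite(out), out, grid.nodata)
    return RasterGrid(
        values=out,
        x0=grid.x0,
        y0=grid.y0,
        cell_size=grid.cell_size * factor,
        nodata=grid.nodata,
        crs=grid.crs,
    )
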