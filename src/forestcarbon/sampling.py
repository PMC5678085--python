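"""Systematic random LiDAR-transect sampling design and design-based inference.

The design overlays a regular grid (nominally 1 degree, converted to the
projected working frame) on a forest mask and places, per grid cell
intersecting forest, one or more rotated-rectangle transects of a target area
(~2000 ha, aspect such that a transect is roughly 1.5 km x 13 km) with a
uniformly random origin among the cell's forest pixels and a uniformly random
heading.  Transects are clusters: the population mean is estimated by the
unweighted mean of cluster means and its variance by the between-cluster
variance, which absorbs the within-transect spatial correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .raster import M_PER_DEG, RasterGrid, read_geojson, write_geojson

log = logging.getLogger(__name__)

#: Skip a grid cell when it holds fewer forest pixels than this.
MIN_FOREST_PIXELS = 10
#: Rejection-sampling cap for origin placement within one cell.
MAX_PLACEMENT_ATTEMPTS = 1000


class DesignError(ValueError):
    pass


@dataclass
class TransectSpec:
    """Design metadata of one transect."""

    origin: tuple[float, float]
    heading_deg: float
    width_m: float
    length_m: float
    grid_cell_id: str
    seed: int


@dataclass
class TransectSet:
    """Transect polygons plus their design metadata."""

    specs: list[TransectSpec]
    polygons: list[Polygon]
    grid_deg: float | None = None
    target_area_ha: float | None = None

    def __len__(self) -> int:
        return len(self.specs)

    def total_area_ha(self) -> float:
        return sum(p.area for p in self.polygons) / 1e4

    def to_geojson(self, path) -> None:
        write_geojson(
            [
                {
                    "geometry": poly,
                    "properties": {
                        "transect_id": i,
                        "heading_deg": spec.heading_deg,
                        "grid_cell_id": spec.grid_cell_id,
                        "seed": spec.seed,
                        "width_m": spec.width_m,
                        "length_m": spec.length_m,
                    },
                }
                for i, (spec, poly) in enumerate(zip(self.specs, self.polygons))
            ],
            path,
        )

    @classmethod
    def from_geojson(cls, path) -> "TransectSet":
        feats = read_geojson(path)
        specs, polys = [], []
        for f in feats:
            p = f["properties"]
            poly = f["geometry"]
            x, y = poly.exterior.coords[0]
            specs.append(
                TransectSpec(
                    origin=(x, y),
                    heading_deg=float(p.get("heading_deg", 0.0)),
                    width_m=float(p.get("width_m", 0.0)),
                    length_m=float(p.get("length_m", 0.0)),
                    grid_cell_id=str(p.get("grid_cell_id", "")),
                    seed=int(p.get("seed", 0)),
                )
            )
            polys.append(poly)
        return cls(specs=specs, polygons=polys)


@dataclass
class DesignEstimate:
    """Design-based estimate of the population mean from clustered samples."""

    mean: float
    se: float
    n_clusters: int
    effective_n: float
    intra_correlation_summary: float = float("nan")


def _transect_polygon(
    origin: tuple[float, float], heading_deg: float, width_m: float, length_m: float
) -> Polygon:
    """Rectangle starting at ``origin``, extending ``length_m`` along the
    heading (degrees clockwise from north), centred across its width."""
    theta = math.radians(heading_deg)
    dx, dy = math.sin(theta), math.cos(theta)  # along-track unit vector
    px, py = math.cos(theta), -math.sin(theta)  # across-track unit vector
    ox, oy = origin
    hw = width_m / 2.0
    ex, ey = ox + length_m * dx, oy + length_m * dy
    return Polygon(
        [
            (ox - hw * px, oy - hw * py),
            (ox + hw * px, oy + hw * py),
            (ex + hw * px, ey + hw * py),
            (ex - hw * px, ey - hw * py),
        ]
    )


def design_transects(
    forest_mask: RasterGrid,
    grid_deg: float = 1.0,
    per_cell: int = 1,
    target_area_ha: float = 2000.0,
    aspect_ratio: float = 8.89,
    seed: int = 0,
    clip_to_extent: bool = True,
    grid_origin: tuple[float, float] | None = None,
) -> TransectSet:
    """Place transects on a grid of ``grid_deg`` degrees over the mask extent.

    For every grid cell holding at least :data:`MIN_FOREST_PIXELS` forest
    pixels, ``per_cell`` transects are drawn: origin uniform over the cell's
    forest pixel centers, heading uniform on [0, 360).  ``aspect_ratio`` is
    length/width; width = sqrt(area / aspect), length = sqrt(area * aspect)
    (the default reproduces a ~1.5 km x ~13.3 km transect at 2000 ha).
    Transects clipped by the analysis extent below 95% of the target area are
    re-drawn (up to :data:`MAX_PLACEMENT_ATTEMPTS`); cells without forest are
    skipped with a warning, never an error.

    ``grid_origin`` is the (x, y of the top-left) anchor of the grid overlay;
    by default the extent corner.  Anchoring the grid to the forested block
    lets a mask with a non-forest margin keep one grid cell per block cell.
    """
    if per_cell < 1:
        raise DesignError("per_cell must be >= 1")
    mask = forest_mask.valid_mask() & (forest_mask.values > 0)
    if not mask.any():
        raise DesignError("forest mask is empty")
    rng = np.random.default_rng(seed)
    spacing = grid_deg * M_PER_DEG
    area_m2 = target_area_ha * 1e4
    width = math.sqrt(area_m2 / aspect_ratio)
    length = math.sqrt(area_m2 * aspect_ratio)

    xmin, ymin, xmax, ymax = forest_mask.bounds
    extent = box(xmin, ymin, xmax, ymax)
    xs, ys = forest_mask.pixel_centers()
    gx0, gy0 = grid_origin if grid_origin is not None else (xmin, ymax)
    ncx = max(1, int(math.ceil((xmax - gx0) / spacing - 1e-9)))
    ncy = max(1, int(math.ceil((gy0 - ymin) / spacing - 1e-9)))

    specs: list[TransectSpec] = []
    polys: list[Polygon] = []
    for gj in range(ncy):
        for gi in range(ncx):
            cx0, cx1 = gx0 + gi * spacing, min(gx0 + (gi + 1) * spacing, xmax)
            cy1, cy0 = gy0 - gj * spacing, max(gy0 - (gj + 1) * spacing, ymin)
            in_cols = (xs >= cx0) & (xs < cx1)
            in_rows = (ys > cy0) & (ys <= cy1)
            sub = mask[np.ix_(in_rows, in_cols)]
            rr, cc = np.nonzero(sub)
            if len(rr) < MIN_FOREST_PIXELS:
                log.warning("grid cell (%d,%d): %d forest pixels, skipped", gi, gj, len(rr))
                continue
            cell_xs = xs[in_cols][cc]
            cell_ys = ys[in_rows][rr]
            cell_id = f"cell_{gi}_{gj}"
            for k in range(per_cell):
                tr_seed = int(rng.integers(0, 2**31 - 1))
                tr_rng = np.random.default_rng(tr_seed)
                placed = False
                for _ in range(MAX_PLACEMENT_ATTEMPTS):
                    i = int(tr_rng.integers(0, len(cell_xs)))
                    heading = float(tr_rng.uniform(0.0, 360.0))
                    poly = _transect_polygon(
                        (float(cell_xs[i]), float(cell_ys[i])), heading, width, length
                    )
                    if clip_to_extent:
                        poly = poly.intersection(extent)
                    if poly.area >= 0.95 * area_m2:
                        placed = True
                        break
                if not placed:
                    log.warning(
                        "grid cell %s: no placement met the area tolerance, skipped",
                        cell_id,
                    )
                    continue
                specs.append(
                    TransectSpec(
                        origin=(float(cell_xs[i]), float(cell_ys[i])),
                        heading_deg=heading,
                        width_m=width,
                        length_m=length,
                        grid_cell_id=cell_id,
                        seed=tr_seed,
                    )
                )
                polys.append(poly)
    if not specs:
        raise DesignError("no transect could be placed on the mask")
    return TransectSet(specs=specs, polygons=polys, grid_deg=grid_deg,
                       target_area_ha=target_area_ha)


def transect_membership(
    raster: RasterGrid, transects: TransectSet, subset=None
) -> np.ndarray:
    """Boolean grid: pixel center inside any (selected) transect polygon."""
    member = np.zeros(raster.shape, dtype=bool)
    xs, ys = raster.pixel_centers()
    idx = range(len(transects)) if subset is None else subset
    for i in idx:
        poly = transects.polygons[i]
        bx0, by0, bx1, by1 = poly.bounds
        cs = np.nonzero((xs >= bx0) & (xs <= bx1))[0]
        rs = np.nonzero((ys >= by0) & (ys <= by1))[0]
        if len(cs) == 0 or len(rs) == 0:
            continue
        gx, gy = np.meshgrid(xs[cs], ys[rs])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        member[np.ix_(rs, cs)] |= inside
    return member


def extract_transect_samples(
    raster: RasterGrid, transects: TransectSet
) -> pd.DataFrame:
    """One record per in-transect, non-nodata pixel (cell-center-in-polygon).

    Returns columns ``transect_id, value, x, y``.  An empty intersection
    yields an empty table, not an error.
    """
    xs, ys = raster.pixel_centers()
    valid = raster.valid_mask()
    frames = []
    for i, poly in enumerate(transects.polygons):
        bx0, by0, bx1, by1 = poly.bounds
        cs = np.nonzero((xs >= bx0) & (xs <= bx1))[0]
        rs = np.nonzero((ys >= by0) & (ys <= by1))[0]
        if len(cs) == 0 or len(rs) == 0:
            continue
        gx, gy = np.meshgrid(xs[cs], ys[rs])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
        sel = inside & valid[np.ix_(rs, cs)]
        if not sel.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "transect_id": i,
                    "value": raster.values[np.ix_(rs, cs)][sel].astype(float),
                    "x": gx[sel],
                    "y": gy[sel],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["transect_id", "value", "x", "y"])
    return pd.concat(frames, ignore_index=True)


def cluster_mean_variance(
    samples: pd.DataFrame,
    variogram=None,
    weight_by_size: bool = False,
) -> DesignEstimate:
    """Design-based mean and standard error from clustered transect samples.

    mean = (un)weighted mean of cluster means; se^2 = between-cluster variance
    of cluster means / n_clusters (equal-area clusters are the design default;
    pixel-count weighting is the documented option).  When a fitted variogram
    is supplied, a within-cluster average correlation and the implied
    effective sample size are reported as diagnostics.
    """
    if samples.empty:
        raise DesignError("no samples")
    groups = samples.groupby("transect_id")
    cluster_means = groups["value"].mean().to_numpy()
    sizes = groups.size().to_numpy()
    n = len(cluster_means)
    if n < 2:
        raise DesignError("variance undefined with a single cluster")
    if weight_by_size:
        w = sizes / sizes.sum()
        mean = float(np.sum(w * cluster_means))
        se = float(np.sqrt(np.sum(w**2 * (cluster_means - mean) ** 2) * n / (n - 1)))
    else:
        mean = float(cluster_means.mean())
        se = float(cluster_means.std(ddof=1) / np.sqrt(n))

    eff_n = float(n)
    rho_summary = float("nan")
    if variogram is not None:
        rhos, effs = [], []
        rng = np.random.default_rng(0)
        for _, g in groups:
            m = len(g)
            if m < 2:
                effs.append(1.0)
                continue
            k = min(m, 200)
            idx = rng.choice(m, size=k, replace=False)
            pts = g.iloc[idx][["x", "y"]].to_numpy()
            from scipy.spatial.distance import pdist

            d = pdist(pts)
            rho = np.mean(variogram.correlation(d)) if len(d) else 0.0
            rho = max(rho, 0.0)
            rhos.append(rho)
            effs.append(m / (1.0 + (m - 1) * rho))
        eff_n = float(np.sum(effs))
        rho_summary = float(np.mean(rhos)) if rhos else float("nan")
    else:
        eff_n = float(sizes.sum())

    return DesignEstimate(
        mean=mean, se=se, n_clusters=n, effective_n=eff_n,
        intra_correlation_summary=rho_summary,
    )
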