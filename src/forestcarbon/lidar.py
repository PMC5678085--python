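"""LiDAR raster metrics: 1-ha MCH aggregation, ordinary-kriging gap fill,
and the height-threshold forest mask.

MCH (mean top canopy height) is the arithmetic mean of the fine-resolution
canopy-height cells inside each 1-ha cell.  Gaps in the fine canopy raster
(cells without adequate ground returns) can be filled by ordinary kriging
under a fitted variogram, which also yields an interpolation-error surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import RasterAlignmentError, RasterGrid, block_mean

log = logging.getLogger(__name__)


@dataclass
class VariogramModel:
    """Fitted semivariogram: gamma(h) = nugget + (sill - nugget) * g(h/range).

    ``range_m`` is the effective range: for the exponential form,
    g(u) = 1 - exp(-3u), so gamma reaches ~95% of the sill at ``range_m``.
    """

    model_form: str
    nugget: float
    sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.model_form not in ("exponential", "spherical"):
            raise ValueError(f"unknown variogram form {self.model_form!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_m <= 0:
            raise ValueError("require 0 <= nugget <= sill and range_m > 0")

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    def gamma(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c1 = self.partial_sill
        if self.model_form == "exponential":
            g = 1.0 - np.exp(-3.0 * h / self.range_m)
        else:  # spherical
            u = np.clip(h / self.range_m, 0.0, 1.0)
            g = 1.5 * u - 0.5 * u**3
        out = self.nugget + c1 * g
        return np.where(h > 0, out, 0.0)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """Process covariance C(h) = sill - gamma(h) (nugget included at 0)."""
        return self.sill - self.gamma(h)

    def correlation(self, h: np.ndarray) -> np.ndarray:
        if self.sill == 0:
            return np.zeros_like(np.asarray(h, dtype=float))
        return self.covariance(h) / self.sill


def aggregate_mch(
    chm_fine: RasterGrid, coarse_cell_m: float, min_valid_fraction: float = 0.5
) -> RasterGrid:
    """Aggregate a fine canopy raster to MCH at ``coarse_cell_m`` resolution.

    Each coarse cell is the mean of its valid fine cells; it is nodata when
    the valid fraction falls below ``min_valid_fraction``.
    """
    factor = coarse_cell_m / chm_fine.cell_size
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise RasterAlignmentError(
            "coarse cell must be an integer multiple of the fine cell"
        )
    return block_mean(chm_fine, int(round(factor)), min_valid_fraction)


def krige_fill(
    chm_fine: RasterGrid,
    variogram: VariogramModel,
    max_neighbors: int = 16,
    search_radius_m: float = 50.0,
) -> tuple[RasterGrid, RasterGrid, pd.DataFrame]:
    """Fill nodata cells by ordinary kriging from nearby valid cells.

    Returns (filled raster, kriging-sd raster, coverage report).  Valid cells
    pass through with sd = sqrt(nugget); nodata cells with no neighbor within
    the search radius stay nodata and are flagged in the coverage report.
    """
    valid = chm_fine.valid_mask()
    filled = np.array(chm_fine.values, dtype=float)
    sd = np.where(valid, np.sqrt(variogram.nugget), np.nan)

    gx, gy = chm_fine.center_grids()
    data_xy = np.column_stack([gx[valid], gy[valid]])
    data_val = chm_fine.values[valid].astype(float)
    rows, cols = np.nonzero(~valid)
    report = []
    if len(rows) and len(data_val):
        tree = cKDTree(data_xy)
        targets = np.column_stack([gx[~valid], gy[~valid]])
        dists, idxs = tree.query(
            targets, k=min(max_neighbors, len(data_val)),
            distance_upper_bound=search_radius_m,
        )
        dists = np.atleast_2d(dists)
        idxs = np.atleast_2d(idxs)
        for t, (r, c) in enumerate(zip(rows, cols)):
            ok = np.isfinite(dists[t])
            if not ok.any():
                report.append((r, c, False, np.nan))
                continue
            nn = idxs[t, ok]
            pred, kvar = _ok_point(
                data_xy[nn], data_val[nn], targets[t], variogram
            )
            filled[r, c] = pred
            sd[r, c] = np.sqrt(max(kvar, 0.0))
            report.append((r, c, True, sd[r, c]))
    else:
        report = [(r, c, False, np.nan) for r, c in zip(rows, cols)]

    sd = np.where(np.isnan(sd), chm_fine.nodata, sd)
    cov = pd.DataFrame(report, columns=["row", "col", "filled", "krige_sd"])
    n_unfilled = int((~cov["filled"]).sum()) if len(cov) else 0
    if n_unfilled:
        log.warning("%d gap cells had no neighbor within the search radius", n_unfilled)
    return chm_fine.like(filled), chm_fine.like(sd), cov


def _ok_point(
    xy: np.ndarray, values: np.ndarray, target: np.ndarray, vg: VariogramModel
) -> tuple[float, float]:
    """Solve the ordinary-kriging system for one target point."""
    n = len(values)
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = vg.gamma(d)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    d0 = np.linalg.norm(xy - target[None, :], axis=-1)
    b = np.empty(n + 1)
    b[:n] = vg.gamma(d0)
    b[n] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(a, b, rcond=None)[0]
    w, mu = sol[:n], sol[n]
    pred = float(w @ values)
    kvar = float(w @ b[:n] + mu)
    return pred, kvar


def forest_mask_from_mch(
    mch: RasterGrid, min_height_m: float = 3.0
) -> tuple[RasterGrid, float]:
    """Binary forest mask (1 where MCH >= threshold) and its area in Mha.

    The >= convention means a cell exactly at the threshold counts as forest.
    Nodata MCH cells are non-forest (0).
    """
    valid = mch.valid_mask()
    mask = (valid & (mch.values >= min_height_m)).astype(float)
    area_mha = mask.sum() * (mch.cell_size**2) / 1e4 / 1e6  # ha -> Mha
    return mch.like(mask), float(area_mha)
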