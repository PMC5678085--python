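"""Environmental-controls analysis: coarse upscaling, ranked variable
importance, and binned mean-response curves with bootstrap standard errors.

Carbon maps are upscaled (block means) to the resolution of climate/soil
layers; a forward-stepwise OLS ranks environmental variables by the adjusted
R^2 they add; binned mean curves summarise each variable's marginal relation
to carbon density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid, block_mean, require_aligned

log = logging.getLogger(__name__)


class EnvControlsError(ValueError):
    pass


def upscale(grid: RasterGrid, factor: int | None = None,
            target_cell_m: float | None = None,
            min_valid_fraction: float = 0.5) -> RasterGrid:
    """Block-mean upscaling to a coarser grid (e.g. 1 ha -> quarter degree).

    Give either an integer ``factor`` or a ``target_cell_m`` that is an
    integer multiple of the source cell.  A finer target is an error.
    """
    if factor is None:
        if target_cell_m is None:
            raise EnvControlsError("give factor or target_cell_m")
        f = target_cell_m / grid.cell_size
        if f < 1 or abs(f - round(f)) > 1e-9:
            raise EnvControlsError(
                "target resolution must be a coarser integer multiple of the source"
            )
        factor = int(round(f))
    if factor < 1:
        raise EnvControlsError("factor must be >= 1; upscaling only")
    return block_mean(grid, int(factor), min_valid_fraction)


def variable_importance(
    carbon: RasterGrid,
    env_stack: dict[str, RasterGrid],
    max_vars: int = 4,
) -> pd.DataFrame:
    """Forward-stepwise ranking of environmental variables.

    At each step the standardized variable that maximises adjusted R^2 of the
    OLS fit is added; per-step and cumulative R^2 (in %) are reported.  A
    candidate adding ~nothing (collinear with earlier picks) is flagged.
    Needs >= 30 jointly valid coarse cells and >= 2 candidates.
    """
    names = list(env_stack)
    if len(names) < 2:
        raise EnvControlsError("need >= 2 candidate variables")
    require_aligned(carbon, *env_stack.values())
    valid = carbon.valid_mask()
    for g in env_stack.values():
        valid &= g.valid_mask()
    n = int(valid.sum())
    if n < 30:
        raise EnvControlsError(f"only {n} jointly valid coarse cells (< 30)")
    y = carbon.values[valid].astype(float)
    x = np.column_stack([env_stack[k].values[valid].astype(float) for k in names])
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) > 0, x.std(axis=0), 1.0)
    y_c = y - y.mean()
    tss = float(y_c @ y_c)
    if tss == 0:
        raise EnvControlsError("carbon has zero variance over valid cells")

    chosen: list[int] = []
    rows = []
    prev_r2 = 0.0
    for _step in range(min(max_vars, len(names))):
        best = None
        for j in range(len(names)):
            if j in chosen:
                continue
            cols = chosen + [j]
            design = np.column_stack([np.ones(n), x[:, cols]])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ coef
            r2 = 1.0 - float(resid @ resid) / tss
            p = len(cols)
            adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - p - 1, 1)
            if best is None or adj > best[1]:
                best = (j, adj, r2)
        j, adj, r2 = best
        gain = r2 - prev_r2
        flagged = gain < 1e-6
        if flagged:
            log.warning("variable %s adds ~no variance (collinear?)", names[j])
        chosen.append(j)
        rows.append(
            {
                "rank": len(chosen),
                "variable": names[j],
                "r2_step_pct": 100.0 * gain,
                "r2_cumulative_pct": 100.0 * r2,
                "adjusted_r2": adj,
                "flagged_collinear": flagged,
            }
        )
        prev_r2 = r2
    return pd.DataFrame(rows)


@dataclass
class BinnedResponse:
    """Binned mean-response curve of carbon against one variable."""

    variable: str
    centers: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.centers,
                "mean_carbon": self.mean,
                "bootstrap_se": self.se,
                "n": self.n,
            }
        )


def binned_means(
    carbon: RasterGrid,
    variable: RasterGrid,
    variable_name: str = "variable",
    n_bins: int = 12,
    n_boot: int = 500,
    seed: int = 0,
) -> BinnedResponse:
    """Mean carbon within equal-width bins of the variable, with bootstrap
    standard errors of each bin mean.  Empty bins are omitted with a log
    flag."""
    if n_bins < 3:
        raise EnvControlsError("n_bins must be >= 3")
    require_aligned(carbon, variable)
    valid = carbon.valid_mask() & variable.valid_mask()
    y = carbon.values[valid].astype(float)
    v = variable.values[valid].astype(float)
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    centers, means, ses, ns = [], [], [], []
    for b in range(n_bins):
        sel = idx == b
        m = int(sel.sum())
        if m == 0:
            log.warning("bin %d of %s is empty; omitted", b, variable_name)
            continue
        yb = y[sel]
        boots = rng.choice(yb, size=(n_boot, m), replace=True).mean(axis=1)
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(yb.mean())
        ses.append(boots.std(ddof=1))
        ns.append(m)
    return BinnedResponse(
        variable=variable_name,
        centers=np.array(centers),
        mean=np.array(means),
        se=np.array(ses),
        n=np.array(ns),
    )
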