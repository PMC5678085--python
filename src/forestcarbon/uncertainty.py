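"""Uncertainty framework: cross-validation schemes, semivariogram analysis,
quadrature error propagation, and region-level model-based inference.

Two cross-validation designs probe the spatial prediction error: random
sample-level folds ("plot-wise") and contiguous latitude-band folds, which
expose the extra error induced by residual spatial autocorrelation.  The
semivariogram machinery estimates nugget/sill/range; the nugget at zero lag
serves as a proxy for sub-pixel geolocation error.  Independent error
components combine in quadrature.  Regional standard errors aggregate pixel
sds under the spatial correlation implied by a fitted variogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

from .lidar import VariogramModel
from .maxent import (
    bin_training_samples,
    fit_maxent_models,
    predict_at_points,
)
from .raster import RasterGrid

log = logging.getLogger(__name__)

MAX_VARIOGRAM_PAIRS = 1_000_000
DENSE_REGION_LIMIT = 10_000


class UncertaintyError(ValueError):
    pass


@dataclass
class ErrorBudget:
    """Independent error components (all sds, same units) and their quadrature
    combination."""

    model_error: float
    geolocation_error: float
    mapping_error: float

    @property
    def combined(self) -> float:
        return propagate_errors(
            [self.model_error, self.geolocation_error, self.mapping_error]
        )


def propagate_errors(components) -> float:
    """Quadrature combination sqrt(sum of squares) of independent error sds."""
    components = np.asarray(list(components), dtype=float)
    if components.size == 0:
        raise UncertaintyError("no error components given")
    if (components < 0).any():
        raise UncertaintyError("error components must be non-negative")
    return float(np.sqrt(np.sum(components**2)))


# -- cross-validation of the spatial prediction ------------------------------

def _cv_metrics(training, covariate_cols, fold_ids, n_bins, beta, background):
    rmses, msds = [], []
    for f in np.unique(fold_ids):
        test = training[fold_ids == f]
        train = training[fold_ids != f]
        if len(test) < 5 or len(train) < 5:
            raise UncertaintyError(f"fold {f} leaves too few samples")
        nb = min(n_bins, max(2, len(train) // 10))
        binning, labeled = bin_training_samples(train, n_bins=nb)
        models = fit_maxent_models(labeled, binning, covariate_cols, background,
                                   beta=beta)
        priors = np.bincount(labeled["bin_id"], minlength=binning.n_bins).astype(float)
        priors /= priors.sum()
        x = test[covariate_cols].to_numpy(dtype=float)
        _, pred, _ = predict_at_points(models, binning, x, priors)
        resid = pred - test["agb"].to_numpy()
        rmses.append(np.sqrt(np.mean(resid**2)))
        msds.append(np.mean(resid))
    rmses, msds = np.array(rmses), np.array(msds)
    return {
        "rmse": float(rmses.mean()),
        "rmse_sd": float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0,
        "msd": float(msds.mean()),
        "msd_sd": float(msds.std(ddof=1)) if len(msds) > 1 else 0.0,
    }


def cv_plotwise(
    training: pd.DataFrame,
    covariate_cols: list[str],
    background: np.ndarray,
    k_folds: int = 5,
    n_bins: int = 10,
    beta: float = 0.05,
    seed: int = 0,
) -> dict:
    """Random sample-level k-fold CV of the full MaxEnt mapping pipeline.

    ``training`` needs columns x, y, agb plus the covariate columns.
    """
    if k_folds < 2:
        raise UncertaintyError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(training)
    folds = rng.permutation(np.arange(n) % k_folds)
    return _cv_metrics(training, covariate_cols, folds, n_bins, beta, background)


def cv_latitudinal(
    training: pd.DataFrame,
    covariate_cols: list[str],
    background: np.ndarray,
    n_bands: int = 5,
    n_bins: int = 10,
    beta: float = 0.05,
    seed: int = 0,
) -> dict:
    """Blocked CV with contiguous latitude bands as folds.

    Bands are equal-count quantile bands of sample latitude (y); each fold
    trains on all other bands.  Under residual spatial autocorrelation this
    scheme yields a larger RMSE than random folds because test samples are
    far from all training samples.
    """
    if n_bands < 2:
        raise UncertaintyError("n_bands must be >= 2")
    y = training["y"].to_numpy(dtype=float)
    if len(np.unique(y)) < n_bands:
        raise UncertaintyError("samples span fewer distinct latitudes than bands")
    qs = np.quantile(y, np.linspace(0, 1, n_bands + 1)[1:-1])
    bands = np.searchsorted(qs, y)
    counts = np.bincount(bands, minlength=n_bands)
    if (counts < 2).any():
        raise UncertaintyError("a latitude band holds fewer than 2 samples")
    return _cv_metrics(training, covariate_cols, bands, n_bins, beta, background)


# -- semivariogram -----------------------------------------------------------

def empirical_semivariogram(
    points: pd.DataFrame,
    lag_edges: np.ndarray,
    max_pairs: int = MAX_VARIOGRAM_PAIRS,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical semivariogram gamma(h) = mean of half squared differences.

    ``points`` needs columns x, y, value.  All pairs are enumerated when the
    point count allows; otherwise pairs are subsampled (seeded) to
    ``max_pairs``.  Empty lag bins are reported with count 0 and NaN gamma.
    """
    lag_edges = np.asarray(lag_edges, dtype=float)
    if len(points) < 2:
        raise UncertaintyError("need at least 2 points")
    if (np.diff(lag_edges) <= 0).any():
        raise UncertaintyError("lag edges must be increasing")
    xy = points[["x", "y"]].to_numpy(dtype=float)
    v = points["value"].to_numpy(dtype=float)
    n = len(v)
    n_all = n * (n - 1) // 2
    if n_all <= max_pairs:
        d = pdist(xy)
        dv = pdist(v[:, None], metric="sqeuclidean")
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=int(max_pairs * 1.2))
        j = rng.integers(0, n, size=int(max_pairs * 1.2))
        keep = i != j
        i, j = i[keep][:max_pairs], j[keep][:max_pairs]
        d = np.hypot(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
        dv = (v[i] - v[j]) ** 2
    which = np.searchsorted(lag_edges, d, side="right") - 1
    ok = (which >= 0) & (which < len(lag_edges) - 1)
    which, d, dv = which[ok], d[ok], dv[ok]
    centers, gammas, counts = [], [], []
    for b in range(len(lag_edges) - 1):
        sel = which == b
        cnt = int(sel.sum())
        centers.append(0.5 * (lag_edges[b] + lag_edges[b + 1]))
        counts.append(cnt)
        gammas.append(0.5 * dv[sel].mean() if cnt else np.nan)
    return pd.DataFrame({"lag": centers, "gamma": gammas, "n_pairs": counts})


def fit_variogram(
    empirical: pd.DataFrame, model_form: str = "exponential"
) -> VariogramModel:
    """Weighted (by pair counts) least-squares fit of nugget, sill and range.

    The nugget is clipped at zero.  A near-zero partial sill (white noise:
    nugget ~ sill, range unidentifiable) is flagged with a warning but
    returned.
    """
    emp = empirical.dropna(subset=["gamma"])
    emp = emp[emp["n_pairs"] > 0]
    if len(emp) < 4:
        raise UncertaintyError("need >= 4 non-empty lags to fit a variogram")
    h = emp["lag"].to_numpy(dtype=float)
    g = emp["gamma"].to_numpy(dtype=float)
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float))

    def shape_fn(hh, r):
        if model_form == "exponential":
            return 1.0 - np.exp(-3.0 * hh / r)
        u = np.clip(hh / r, 0.0, 1.0)
        return 1.5 * u - 0.5 * u**3

    def resid(theta):
        c0, c1, r = theta
        return w * (c0 + c1 * shape_fn(h, r) - g)

    gmax = g.max()
    x0 = np.array([max(g[0], 1e-6 * gmax + 1e-12), max(gmax - g[0], 1e-6), h.max() / 2])
    sol = least_squares(
        resid, x0,
        bounds=([0.0, 0.0, h.min() * 1e-3], [np.inf, np.inf, h.max() * 100]),
        max_nfev=10_000,
    )
    if not sol.success:
        raise UncertaintyError(f"variogram fit failed: {sol.message}")
    c0, c1, r = sol.x
    if c1 < 1e-10 * max(c0, 1.0):
        log.warning("variogram is pure nugget; range is unidentifiable")
    return VariogramModel(model_form=model_form, nugget=float(c0),
                          sill=float(c0 + c1), range_m=float(r))


def covariance_ratio(
    map_variogram: VariogramModel, residual_variogram: VariogramModel
) -> float:
    """Ratio of residual to map partial sill (spatially structured variance
    retained by the residuals)."""
    if map_variogram.partial_sill <= 0:
        raise UncertaintyError("map variogram has zero partial sill")
    return residual_variogram.partial_sill / map_variogram.partial_sill


# -- regional model-based inference ------------------------------------------

def regional_inference(
    mean_map: RasterGrid,
    sd_map: RasterGrid,
    region_mask: np.ndarray,
    variogram: VariogramModel | None = None,
    dense_limit: int = DENSE_REGION_LIMIT,
    max_pairs: int = 100_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Regional mean, standard error and relative error (%) from pixel sds.

    se^2 = (1/n^2) sum_ij rho(h_ij) s_i s_j, the model-based aggregation of
    pixel uncertainties under the correlation implied by the variogram.  The
    quadratic form is evaluated densely for regions up to ``dense_limit``
    pixels; above that the effective-sample-size approximation
    n_eff = n / (1 + (n - 1) rho_bar) is used with rho_bar estimated from a
    seeded subsample of pixel pairs.  Without a variogram pixels are treated
    as uncorrelated.
    """
    valid = mean_map.valid_mask() & sd_map.valid_mask() & region_mask.astype(bool)
    n = int(valid.sum())
    if n == 0:
        raise UncertaintyError("region contains no valid map pixels")
    vals = mean_map.values[valid].astype(float)
    sds = sd_map.values[valid].astype(float)
    mean = float(vals.mean())

    if variogram is None:
        se = float(np.sqrt(np.sum(sds**2)) / n)
    else:
        gx, gy = mean_map.center_grids()
        xy = np.column_stack([gx[valid], gy[valid]])
        if n <= dense_limit:
            from scipy.spatial.distance import squareform

            rho = variogram.correlation(squareform(pdist(xy)))
            np.fill_diagonal(rho, 1.0)
            rho = np.maximum(rho, 0.0)
            se = float(np.sqrt(sds @ rho @ sds) / n)
        else:
            rng = np.random.default_rng(seed)
            i = rng.integers(0, n, size=max_pairs)
            j = rng.integers(0, n, size=max_pairs)
            keep = i != j
            d = np.hypot(*(xy[i[keep]] - xy[j[keep]]).T)
            rho_bar = float(np.maximum(variogram.correlation(d), 0.0).mean())
            n_eff = n / (1.0 + (n - 1) * rho_bar)
            se = float(np.sqrt(np.mean(sds**2) / n_eff))
    rel = 100.0 * se / mean if mean != 0 else float("inf")
    return mean, se, rel
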