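"""Continuous-response maximum-entropy biomass mapping.

Transect-level 1-ha AGB samples are discretised into biomass bins.  For each
bin, a maximum-entropy (Gibbs) density over the covariate background is
fitted: p(x) proportional to exp(lambda . f(x)), where f(x) are normalized
feature expansions (linear, quadratic, pairwise products; hinge optional) and
the weights maximise the L1-penalised log-likelihood of the bin's presence
pixels against the background.  The per-bin densities are combined through
Bayes' rule with the training bin proportions as priors, giving at every
pixel a posterior over biomass bins and hence a predictive mean and standard
deviation (between-bin spread plus, by default, the within-bin sample
variance).

This is the in-package realisation of a "modified MaxEnt" continuous-response
estimator: the discretisation, feature classes and regularisation are design
choices documented in docs/methods.md, not claims about any particular
published MaxEnt software.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .raster import RasterGrid, require_aligned

log = logging.getLogger(__name__)

DEFAULT_N_BINS = 15
DEFAULT_BETA = 0.05
MAX_BACKGROUND = 50_000


class MaxEntError(ValueError):
    pass


@dataclass
class BiomassBinning:
    """Discretisation of the AGB axis used by the per-bin density models."""

    edges: np.ndarray
    centers: np.ndarray
    strategy: str
    within_bin_var: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, agb: np.ndarray) -> np.ndarray:
        """Bin index per sample; values at the upper edge fall in the last bin."""
        idx = np.searchsorted(self.edges, np.asarray(agb, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def bin_training_samples(
    samples: pd.DataFrame,
    n_bins: int = DEFAULT_N_BINS,
    strategy: str = "quantile",
) -> tuple[BiomassBinning, pd.DataFrame]:
    """Bin training samples by AGB; centers are in-bin median AGB.

    ``samples`` must carry a column ``agb``.  The quantile strategy yields
    near-equal bin counts; equal_width splits the observed range evenly.
    """
    if n_bins < 2:
        raise MaxEntError("n_bins must be >= 2")
    agb = samples["agb"].to_numpy(dtype=float)
    if len(np.unique(agb)) < n_bins:
        raise MaxEntError(
            f"need >= {n_bins} distinct AGB values, got {len(np.unique(agb))}"
        )
    if strategy == "quantile":
        edges = np.quantile(agb, np.linspace(0.0, 1.0, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < n_bins + 1:
            raise MaxEntError("quantile edges degenerate; reduce n_bins")
    elif strategy == "equal_width":
        edges = np.linspace(agb.min(), agb.max(), n_bins + 1)
    else:
        raise MaxEntError(f"unknown binning strategy {strategy!r}")
    idx = np.clip(np.searchsorted(edges, agb, side="right") - 1, 0, n_bins - 1)
    centers = np.array([np.median(agb[idx == k]) for k in range(n_bins)])
    wvar = np.array(
        [np.var(agb[idx == k]) if (idx == k).sum() > 1 else 0.0 for k in range(n_bins)]
    )
    labeled = samples.copy()
    labeled["bin_id"] = idx
    return BiomassBinning(edges=edges, centers=centers, strategy=strategy,
                          within_bin_var=wvar), labeled


@dataclass
class FeatureSpec:
    """Feature expansion and its normalization bounds (from background only)."""

    classes: tuple[str, ...] = ("linear", "quadratic", "product")
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    hinge_knots: int = 4

    def fit_bounds(self, background: np.ndarray) -> "FeatureSpec":
        lo = background.min(axis=0)
        hi = background.max(axis=0)
        hi = np.where(hi > lo, hi, lo + 1.0)
        return FeatureSpec(classes=self.classes, lo=lo, hi=hi,
                           hinge_knots=self.hinge_knots)

    def expand(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and the per-feature class index (for per-class beta)."""
        if self.lo is None:
            raise MaxEntError("feature bounds not fitted; call fit_bounds first")
        z = np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        feats, cls = [], []
        if "linear" in self.classes:
            feats.append(z)
            cls += [0] * z.shape[1]
        if "quadratic" in self.classes:
            feats.append(z**2)
            cls += [1] * z.shape[1]
        if "product" in self.classes and z.shape[1] > 1:
            prods = [
                z[:, i] * z[:, j]
                for i in range(z.shape[1])
                for j in range(i + 1, z.shape[1])
            ]
            feats.append(np.column_stack(prods))
            cls += [2] * len(prods)
        if "hinge" in self.classes:
            knots = np.linspace(0.0, 1.0, self.hinge_knots + 2)[1:-1]
            hinges = [np.maximum(z[:, i] - k, 0.0) for i in range(z.shape[1]) for k in knots]
            feats.append(np.column_stack(hinges))
            cls += [3] * len(hinges)
        return np.column_stack(feats), np.asarray(cls)


@dataclass
class MaxEntModel:
    """One bin's fitted Gibbs density over the covariate background."""

    bin_id: int
    weights: np.ndarray
    spec: FeatureSpec
    beta: np.ndarray  # per-feature penalty actually applied
    log_partition: float  # log sum over background of exp(w . f)
    converged: bool = True

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Log density relative to the uniform background counting measure."""
        f, _ = self.spec.expand(x)
        return f @ self.weights - self.log_partition

    def to_dict(self) -> dict:
        return {
            "bin_id": self.bin_id,
            "weights": self.weights.tolist(),
            "log_partition": self.log_partition,
            "converged": self.converged,
        }


@dataclass
class AGBMap:
    """Predicted biomass map: mean and sd rasters, optional bin posteriors."""

    mean: RasterGrid
    sd: RasterGrid
    bin_posteriors: np.ndarray | None = None  # (n_bins, nrow, ncol)


def _penalized_negloglik(w, f_presence_mean, f_bg, beta):
    gains = f_bg @ w
    return -(f_presence_mean @ w) + logsumexp(gains), None


def fit_maxent_bin(
    presence: np.ndarray,
    background: np.ndarray,
    spec: FeatureSpec | None = None,
    beta: float | dict = DEFAULT_BETA,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MaxEntModel:
    """Fit one bin's penalised maximum-entropy density.

    Maximises  mean_presence(w.f) - log sum_background exp(w.f) - sum beta_j |w_j|
    via L-BFGS-B on the positive/negative split of w (the L1 term becomes
    linear, keeping the objective smooth).  ``beta`` is a scalar applied to
    every feature class or a dict keyed by class name.

    At the optimum the regularised moment-matching condition
    |E_presence[f_j] - E_model[f_j]| <= beta_j holds elementwise.
    """
    presence = np.asarray(presence, dtype=float)
    background = np.asarray(background, dtype=float)
    if presence.ndim == 1:
        presence = presence[:, None]
    if background.ndim == 1:
        background = background[:, None]
    if not (np.isfinite(presence).all() and np.isfinite(background).all()):
        raise MaxEntError("non-finite feature values")
    if len(presence) < 5:
        raise MaxEntError("need >= 5 presence pixels")
    if spec is None or spec.lo is None:
        spec = (spec or FeatureSpec()).fit_bounds(background)

    f_p, cls = spec.expand(presence)
    f_b, _ = spec.expand(background)
    fp_mean = f_p.mean(axis=0)
    class_names = ("linear", "quadratic", "product", "hinge")
    if isinstance(beta, dict):
        beta_j = np.array([beta.get(class_names[c], DEFAULT_BETA) for c in cls])
    else:
        beta_j = np.full(len(cls), float(beta))

    m = f_b.shape[1]

    def objective(uv):
        w = uv[:m] - uv[m:]
        gains = f_b @ w
        lz = logsumexp(gains)
        nll = -(fp_mean @ w) + lz + beta_j @ (uv[:m] + uv[m:])
        p = np.exp(gains - lz)
        grad_w = -fp_mean + f_b.T @ p
        grad = np.concatenate([grad_w + beta_j, -grad_w + beta_j])
        return nll, grad

    uv0 = np.zeros(2 * m)
    res = minimize(
        objective, uv0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * m),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    w = res.x[:m] - res.x[m:]
    converged = bool(res.success)
    if not converged:
        log.warning("maxent bin fit did not converge: %s", res.message)
    lz = float(logsumexp(f_b @ w))
    return MaxEntModel(bin_id=-1, weights=w, spec=spec, beta=beta_j,
                       log_partition=lz, converged=converged)


def fit_maxent_models(
    labeled: pd.DataFrame,
    binning: BiomassBinning,
    covariate_cols: list[str],
    background: np.ndarray,
    beta: float | dict = DEFAULT_BETA,
    min_presence: int = 5,
) -> list[MaxEntModel]:
    """Fit the per-bin density models on shared background bounds."""
    spec = FeatureSpec().fit_bounds(background)
    models = []
    for k in range(binning.n_bins):
        pres = labeled.loc[labeled["bin_id"] == k, covariate_cols].to_numpy(dtype=float)
        if len(pres) < min_presence:
            raise MaxEntError(f"bin {k} has {len(pres)} presence pixels (< {min_presence})")
        model = fit_maxent_bin(pres, background, spec=spec, beta=beta)
        model.bin_id = k
        models.append(model)
    return models


def predict_at_points(
    models: list[MaxEntModel],
    binning: BiomassBinning,
    x: np.ndarray,
    priors: np.ndarray,
    include_within_bin_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior over bins, predictive mean and sd at feature rows ``x``."""
    priors = np.asarray(priors, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-8:
        raise MaxEntError("priors must sum to 1")
    loglik = np.column_stack([m.log_density(x) for m in models])
    logpost = loglik + np.log(np.maximum(priors, 1e-300))[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    centers = binning.centers
    mean = post @ centers
    var = np.einsum("nk,nk->n", post, (centers[None, :] - mean[:, None]) ** 2)
    if include_within_bin_var:
        var = var + post @ binning.within_bin_var
    return post, mean, np.sqrt(var)


def predict_map(
    models: list[MaxEntModel],
    binning: BiomassBinning,
    covariates: list[RasterGrid],
    priors: np.ndarray,
    include_within_bin_var: bool = True,
    keep_posteriors: bool = False,
) -> AGBMap:
    """Wall-to-wall prediction over a covariate stack.

    Pixels with any nodata covariate are nodata in both outputs.
    """
    require_aligned(*covariates)
    ref = covariates[0]
    valid = np.ones(ref.shape, dtype=bool)
    for c in covariates:
        valid &= c.valid_mask()
    x = np.column_stack([c.values[valid].astype(float) for c in covariates])
    post, mean, sd = predict_at_points(
        models, binning, x, priors, include_within_bin_var
    )
    mean_r = np.full(ref.shape, ref.nodata, dtype=float)
    sd_r = np.full(ref.shape, ref.nodata, dtype=float)
    mean_r[valid] = mean
    sd_r[valid] = sd
    posts = None
    if keep_posteriors:
        posts = np.full((binning.n_bins,) + ref.shape, np.nan)
        for k in range(binning.n_bins):
            layer = np.full(ref.shape, np.nan)
            layer[valid] = post[:, k]
            posts[k] = layer
    return AGBMap(mean=ref.like(mean_r), sd=ref.like(sd_r), bin_posteriors=posts)


def map_evaluation(
    agb_map: AGBMap, reference: pd.DataFrame
) -> tuple[float, float, pd.DataFrame]:
    """RMSE and mean signed deviation (predicted - observed) of the map mean
    against reference pixels (columns x, y, agb)."""
    row, col = agb_map.mean.index_of(
        reference["x"].to_numpy(), reference["y"].to_numpy()
    )
    nrow, ncol = agb_map.mean.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    if not inside.any():
        raise MaxEntError("no reference pixel falls inside the map")
    pred = agb_map.mean.values[row[inside], col[inside]]
    obs = reference["agb"].to_numpy()[inside]
    ok = pred != agb_map.mean.nodata
    if not ok.any():
        raise MaxEntError("all overlapping map pixels are nodata")
    resid = pred[ok] - obs[ok]
    scatter = pd.DataFrame(
        {
            "x": reference["x"].to_numpy()[inside][ok],
            "y": reference["y"].to_numpy()[inside][ok],
            "observed": obs[ok],
            "predicted": pred[ok],
        }
    )
    return float(np.sqrt(np.mean(resid**2))), float(np.mean(resid)), scatter


def save_models(models: list[MaxEntModel], binning: BiomassBinning, path) -> None:
    doc = {
        "edges": binning.edges.tolist(),
        "centers": binning.centers.tolist(),
        "within_bin_var": binning.within_bin_var.tolist(),
        "strategy": binning.strategy,
        "models": [m.to_dict() for m in models],
    }
    Path(path).write_text(json.dumps(doc))
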