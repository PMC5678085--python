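"""Synthetic landscape and observation-process generators.

The downstream pipeline (transect sampling, power-law biomass fitting,
maximum-entropy mapping, uncertainty analysis) is exercised against
landscapes whose truth is known.  The generator reproduces the statistical
structure the real analysis relies on:

* a spatially autocorrelated mean-canopy-height (MCH) field with an
  approximately exponential covariance of configurable range/sill/nugget;
* forest-type-dependent wood density (humid-forest mean around 0.66 g cm^-3);
* covariates that are noisy monotone transforms of height, including a
  radar-like band that saturates above a configurable height, so that the
  covariates only weakly identify high biomass;
* fine-resolution (e.g. 2 m) canopy rasters inside the flown transects,
  with ground-return gaps;
* 1-ha ground plots whose observed biomass carries measurement noise.

True aboveground biomass follows the wood-density-weighted power law
``AGB = a * (WD * h) ** b`` with multiplicative lognormal noise whose log
has mean zero, i.e. the forward model matches the linearised log-space fit
used by the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid, NODATA

#: Default power-law scale and exponent of the biomass forward model
#: (Mg ha^-1 per (g cm^-3 m)^b, dimensionless).
DEFAULT_A = 10.43
DEFAULT_B = 1.19

#: Humid-forest mean wood density, g cm^-3.
DEFAULT_WD_MEAN = 0.66


class ConfigurationError(ValueError):
    """Invalid landscape configuration."""


@dataclass
class CovariateSpec:
    """One synthetic covariate: a transform of height plus independent noise.

    transform: 'linear', 'log1p' or 'saturating'.  The saturating transform is
    ``L * (1 - exp(-h / h_sat))``, mimicking radar backscatter saturation.
    """

    name: str
    transform: str = "linear"
    noise_sd: float = 0.0
    saturation_height_m: float | None = None
    scale: float = 1.0

    def apply(self, height: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.transform == "linear":
            base = self.scale * height
        elif self.transform == "log1p":
            base = self.scale * np.log1p(height)
        elif self.transform == "saturating":
            if self.saturation_height_m is None or self.saturation_height_m <= 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: saturating transform needs a "
                    "positive saturation_height_m"
                )
            base = self.scale * (1.0 - np.exp(-height / self.saturation_height_m))
        else:
            raise ConfigurationError(f"unknown covariate transform {self.transform!r}")
        if self.noise_sd > 0:
            base = base + rng.normal(0.0, self.noise_sd, size=height.shape)
        return base


def _default_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("optical", transform="log1p", noise_sd=0.15, scale=1.0),
        CovariateSpec(
            "radar", transform="saturating", noise_sd=0.05,
            saturation_height_m=15.0, scale=1.0,
        ),
        CovariateSpec("terrain", transform="linear", noise_sd=4.0, scale=0.5),
    ]


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Heights are generated as midpoint(height_range_m) plus a zero-mean
    stationary field of exponential covariance (sill, spatial_range_m) plus
    iid nugget noise, clipped into height_range_m.  Wood density is drawn per
    forest type; biomass follows the power law with lognormal noise of the
    given coefficient of variation.
    """

    extent_cells: tuple[int, int] = (100, 100)
    cell_size_m: float = 100.0
    height_range_m: tuple[float, float] = (0.0, 60.0)
    spatial_range_m: float = 3000.0
    sill: float = 25.0
    nugget: float = 1.0
    n_forest_types: int = 3
    wd_by_type: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.66, 0.05), (0.58, 0.05), (0.45, 0.04)]
    )
    covariate_specs: list[CovariateSpec] = field(default_factory=_default_covariates)
    agb_a: float = DEFAULT_A
    agb_b: float = DEFAULT_B
    agb_noise_cv: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        nrow, ncol = self.extent_cells
        if nrow <= 0 or ncol <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        lo, hi = self.height_range_m
        if lo < 0 or hi <= lo:
            raise ConfigurationError("height_range_m must satisfy 0 <= min < max")
        if self.spatial_range_m <= 0:
            raise ConfigurationError("spatial_range_m must be positive")
        if self.sill < 0 or self.nugget < 0:
            raise ConfigurationError("sill and nugget must be non-negative")
        if self.n_forest_types < 1 or len(self.wd_by_type) < self.n_forest_types:
            raise ConfigurationError("need a (mean, sd) wood density per forest type")
        for mean, _sd in self.wd_by_type[: self.n_forest_types]:
            if not 0.1 < mean < 1.2:
                raise ConfigurationError("wood density means must lie in (0.1, 1.2)")
        if self.agb_noise_cv < 0:
            raise ConfigurationError("agb_noise_cv must be non-negative")


@dataclass
class TrueState:
    """The generated truth: all layers share one grid."""

    height: RasterGrid
    wood_density: RasterGrid
    agb_true: RasterGrid
    forest_type: RasterGrid
    covariates: list[RasterGrid]
    covariate_names: list[str]


# -- random-field synthesis --------------------------------------------------

def exponential_field(
    shape: tuple[int, int],
    cell_size: float,
    range_m: float,
    sill: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean stationary Gaussian field with covariance
    ``C(h) = sill * exp(-3 h / range_m)`` (range_m is the effective range at
    which correlation drops to ~5%).

    Synthesised spectrally by circulant embedding on a doubled torus; the few
    slightly negative embedding eigenvalues of the exponential kernel are
    clipped at zero, which perturbs the target covariance negligibly at these
    domain sizes.
    """
    if sill <= 0:
        return np.zeros(shape)
    nrow, ncol = shape
    er, ec = 2 * nrow, 2 * ncol
    iy = np.minimum(np.arange(er), er - np.arange(er))
    ix = np.minimum(np.arange(ec), ec - np.arange(ec))
    d = cell_size * np.hypot(iy[:, None], ix[None, :])
    cov = sill * np.exp(-3.0 * d / range_m)
    eig = np.fft.fft2(cov).real
    eig = np.maximum(eig, 0.0)
    n_emb = er * ec
    noise = rng.normal(size=(er, ec)) + 1j * rng.normal(size=(er, ec))
    f = np.fft.fft2(noise * np.sqrt(eig / n_emb) / np.sqrt(2.0))
    sim = np.sqrt(2.0) * f.real[:nrow, :ncol]
    return sim


def generate_height_field(config: LandscapeConfig) -> RasterGrid:
    """Mean-canopy-height field: midpoint + correlated field + nugget noise,
    clipped into ``height_range_m``.  Deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.height_range_m
    mid = 0.5 * (lo + hi)
    z = exponential_field(
        config.extent_cells, config.cell_size_m, config.spatial_range_m,
        config.sill, rng,
    )
    if config.nugget > 0:
        z = z + rng.normal(0.0, np.sqrt(config.nugget), size=config.extent_cells)
    h = np.clip(mid + z, lo, hi)
    return RasterGrid(values=h, x0=0.0, y0=config.extent_cells[0] * config.cell_size_m,
                      cell_size=config.cell_size_m)


def generate_true_state(config: LandscapeConfig) -> TrueState:
    """Full landscape truth: height, forest type, wood density, biomass and
    covariates, all deterministic for a fixed seed."""
    config.validate()
    height = generate_height_field(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    # forest types: quantile slices of an independent smooth field, so types
    # form contiguous patches rather than salt-and-pepper noise
    tfield = exponential_field(
        config.extent_cells, config.cell_size_m,
        2.0 * config.spatial_range_m, 1.0, rng,
    )
    qs = np.quantile(tfield, np.linspace(0, 1, config.n_forest_types + 1)[1:-1])
    ftype = np.searchsorted(qs, tfield).astype(float)

    wd = np.empty(config.extent_cells)
    for t in range(config.n_forest_types):
        mean, sd = config.wd_by_type[t]
        sel = ftype == t
        wd[sel] = mean + rng.normal(0.0, sd, size=int(sel.sum()))
    wd = np.clip(wd, 0.101, 1.199)

    h = height.values
    agb = config.agb_a * np.power(wd * h, config.agb_b)
    if config.agb_noise_cv > 0:
        sigma_log = np.sqrt(np.log1p(config.agb_noise_cv**2))
        agb = agb * rng.lognormal(0.0, sigma_log, size=agb.shape)
    agb = np.where(h > 0, agb, 0.0)

    covs, names = [], []
    for spec in config.covariate_specs:
        covs.append(height.like(spec.apply(h, rng)))
        names.append(spec.name)

    return TrueState(
        height=height,
        wood_density=height.like(wd),
        agb_true=height.like(agb),
        forest_type=height.like(ftype),
        covariates=covs,
        covariate_names=names,
    )


# -- observation processes ---------------------------------------------------

def simulate_lidar_chm(
    state: TrueState,
    transects,
    footprint_m: float,
    gap_fraction: float = 0.0,
    texture_sd: float = 0.0,
    seed: int = 0,
):
    """Fine-resolution canopy height model restricted to transect footprints.

    Each coarse cell's height is replicated onto ``footprint_m`` sub-cells with
    optional Gaussian texture noise; a random ``gap_fraction`` of in-transect
    fine cells is set to nodata, emulating regions without adequate ground
    returns.  Fine cells outside every transect are nodata.

    ``transects`` is a :class:`~forestcarbon.sampling.TransectSet`.
    """
    from .sampling import transect_membership  # local import; avoids cycle

    if not 0.0 <= gap_fraction < 1.0:
        raise ConfigurationError("gap_fraction must be in [0, 1)")
    coarse = state.height
    factor = coarse.cell_size / footprint_m
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ConfigurationError("footprint_m must divide the coarse cell size")
    factor = int(round(factor))

    xmin, ymin, xmax, ymax = coarse.bounds
    for poly in transects.polygons:
        bx0, by0, bx1, by1 = poly.bounds
        if bx1 < xmin or bx0 > xmax or by1 < ymin or by0 > ymax:
            raise ValueError("transect lies outside the raster extent")

    rng = np.random.default_rng(seed)
    fine_vals = np.repeat(np.repeat(coarse.values, factor, 0), factor, 1)
    fine = RasterGrid(values=fine_vals.astype(float), x0=coarse.x0, y0=coarse.y0,
                      cell_size=footprint_m, nodata=NODATA)
    inside = transect_membership(fine, transects)
    out = np.full(fine.shape, NODATA)
    vals = fine.values[inside]
    if texture_sd > 0:
        vals = vals + rng.normal(0.0, texture_sd, size=vals.shape)
    if gap_fraction > 0:
        gaps = rng.random(vals.shape) < gap_fraction
        vals = np.where(gaps, NODATA, vals)
    out[inside] = vals
    return fine.like(out)


def simulate_ground_plots(
    state: TrueState,
    transects,
    n_plots: int,
    obs_noise_sd: float = 0.0,
    transect_fraction: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground inventory plots inside a random subset of transects.

    ``ceil(transect_fraction * n_transects)`` transects are chosen, then
    ``n_plots`` distinct 1-ha cells are drawn uniformly from their union.
    Observed biomass is truth plus additive Gaussian noise truncated at zero;
    wood density and MCH are read from the truth layers.
    """
    from .sampling import transect_membership

    if n_plots < 2:
        raise ConfigurationError("n_plots must be at least 2")
    rng = np.random.default_rng(seed)
    n_tr = len(transects)
    n_sub = max(1, int(np.ceil(transect_fraction * n_tr)))
    chosen = rng.choice(n_tr, size=n_sub, replace=False)
    member = transect_membership(state.height, transects, subset=chosen)
    rows, cols = np.nonzero(member)
    if len(rows) < n_plots:
        raise ValueError(
            f"only {len(rows)} in-transect cells available for {n_plots} plots"
        )
    pick = rng.choice(len(rows), size=n_plots, replace=False)
    r, c = rows[pick], cols[pick]
    xs, ys = state.height.pixel_centers()
    agb_true = state.agb_true.values[r, c]
    obs = agb_true + (
        rng.normal(0.0, obs_noise_sd, size=n_plots) if obs_noise_sd > 0 else 0.0
    )
    return pd.DataFrame(
        {
            "plot_id": [f"plot_{i:04d}" for i in range(n_plots)],
            "x": xs[c],
            "y": ys[r],
            "agb_obs": np.maximum(obs, 0.0),
            "wd_mean": state.wood_density.values[r, c],
            "mch": state.height.values[r, c],
        }
    )
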