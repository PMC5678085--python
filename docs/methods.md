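# Methods

This note documents the models implemented in `forestcarbon`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter for reproducing results.

## Scope and design

The package implements a complete airborne-LiDAR forest-carbon estimation
chain as a library (`src/forestcarbon`) plus a numbered analysis narrative
(`analysis/`).  Every quantitative claim in the analysis scripts and the
acceptance script is computed at run time by the library; nothing is looked
up.  Because no real LiDAR, satellite or plot data ship with the package,
every stage is exercised against synthetic landscapes whose truth is known,
which turns each stage into a testable estimator-recovery problem.

## Synthetic landscapes

`LandscapeConfig` + `generate_true_state` produce:

* **Canopy height (MCH).**  midpoint(height_range) + Z + ε, where Z is a
  zero-mean stationary Gaussian field with exponential covariance
  C(h) = sill·exp(−3h/range) and ε is iid N(0, nugget), clipped into
  `height_range_m`.  Defaults: range 3 km, sill 25 m², nugget 1 m², heights
  in [0, 60] m — giving a realistic humid-forest height distribution with
  clipping rare enough (≈6 sd from the bounds) not to distort the
  covariance.  The field is synthesised by circulant embedding on a doubled
  torus; the handful of negative embedding eigenvalues of the exponential
  kernel are clipped at zero, a perturbation far below sampling noise at
  these domain sizes.  `range_m` is everywhere the *effective* range (the
  distance at which correlation decays to ~5%), for both the generator and
  the variogram fitter, so round-trip recovery is well defined.
* **Wood density.**  Forest types are quantile slices of an independent
  smooth field (contiguous patches, not salt-and-pepper); per type
  WD ~ N(mean, sd) clipped to (0.1, 1.2) g cm⁻³, defaults
  (0.66, 0.58, 0.45) ± 0.05 — a humid-forest mean of 0.66 g cm⁻³ with
  lighter-wood types toward drier formations.
* **Biomass truth.**  AGB = a (WD·h)^b · ε with a = 10.43, b = 1.19 and
  multiplicative lognormal noise with E[ln ε] = 0, parameterised by a
  coefficient of variation (default 20%).  The log-mean-zero convention
  matches the linearised log-space fit of the estimator, so the fit is
  asymptotically unbiased for (ln a, b) by construction and the recovery
  tests probe finite-sample behaviour only.  AGB is exactly 0 where h = 0.
* **Covariates.**  Noisy monotone transforms of height: a log-like
  "optical" band, a linear "terrain" band, and a radar-like band
  L(1 − exp(−h/h_sat)) with h_sat = 15 m, saturating in exactly the way
  that makes high-biomass pixels weakly identified — the central difficulty
  the mapping stage must cope with.
* **Observation processes.**  The fine-resolution canopy model replicates
  each 1-ha cell onto the fine grid inside transect footprints, adds
  within-cell texture noise, and knocks out a configurable fraction of fine
  cells (ground-return gaps).  Ground plots are distinct 1-ha cells drawn
  uniformly inside a random subset (default 15%) of transects; observed AGB
  is truth + additive Gaussian noise truncated at zero (default sd
  52 Mg ha⁻¹).  The additive plot-error model is a deliberate choice — it is
  the natural reading of a plot-level residual scale — and it is *mis*matched
  to the multiplicative fit on purpose; see Limitations.

Not emulated: waveform/point-cloud LiDAR physics, tree-level stand
structure, sensor geometry, cloud/terrain artefacts, or land-cover
classification error.  Passing tests therefore demonstrate statistical
correctness of the estimators under the stated stochastic model, not
robustness to real-sensor pathologies.

## Sampling design and design-based inference

A grid of `grid_deg` degrees (converted at 111.32 km/degree in a projected
equal-area working frame) is overlaid on the forest mask; each cell holding
at least 10 forest pixels receives `per_cell` transects with origin uniform
over the cell's forest pixel centers and heading uniform on [0, 360).
Transects are rectangles of the target area (default 2000 ha) at
length/width ratio 8.89 (≈1.5 km × 13.3 km).  Placement is by rejection:
a draw whose polygon, after clipping to the analysis extent, falls below
95% of the target area is redrawn (cap 1000 attempts, then the cell is
skipped with a warning).  The grid can be anchored (`grid_origin`) so that
a mask with a non-forest margin keeps exactly one grid cell per forest
block.

The cluster estimator treats transects as equal-weight primary sampling
units (the design fixes transect area): mean = mean of cluster means,
se² = var(cluster means)/n.  Pixel-count weighting is available as an
option.  With a fitted variogram the estimator also reports a
within-cluster average correlation ρ̄ and the implied effective sample size
Σ nᵢ/(1 + (nᵢ−1)ρ̄ᵢ) as a diagnostic (computed on a ≤200-point subsample
per cluster).  Coverage of the nominal 95% interval is verified by Monte
Carlo over 500 seeded designs on a fixed landscape; the experiment uses
scaled-down transects (200 ha on a 5-km grid, 25 clusters) — the
coverage property is scale-free, and these sizes keep the experiment
desk-sized.

## LiDAR metrics

MCH is the arithmetic mean of valid fine cells per coarse cell; a coarse
cell is nodata below a 50% valid fraction.  Gap filling is local ordinary
kriging (default 16 neighbours within 50 m at 2-m resolution): per target
the standard OK system with Lagrange multiplier is solved; weights sum to 1
by construction, prediction at a datum with zero nugget is exact with zero
variance, and unreachable cells stay nodata and are flagged in a coverage
report.  The default variogram form is exponential; spherical is available.
The forest mask is MCH ≥ 3 m by default (≥ convention at the boundary);
the threshold is configuration, not a claim about any jurisdiction's legal
forest definition.

## Power-law biomass estimator

`fit_power_law` is OLS of ln AGB on ln(WD·h); σ_log is the residual sd
(dof n−2).  Plots with zero AGB or zero MCH cannot enter the log fit and
are excluded and counted.  The back-transform bias correction
exp(σ²_log/2) is exposed but OFF by default, matching the literal power-law
form; recovery tests accept either convention applied consistently.
Cross-validation uses repeated random 80/20 splits *without* replacement
(subsampling, the natural reading of a repeated-split scheme; a
with-replacement bootstrap of the training side is an option).  Mean signed
deviation is defined as mean(predicted − observed) throughout the package.

## MaxEnt mapping

The continuous response is discretised into AGB bins (default 15 quantile
bins; centers = in-bin median; within-bin variance recorded).  Features are
min-max normalised using *background* bounds only, then expanded into
linear, quadratic and pairwise-product classes (hinge features available,
off by default — the smallest feature set for which the brute-force oracle
tests are exact).  Per bin, weights maximise

  mean_presence(λ·f) − log Σ_background exp(λ·f) − Σ_j β_j |λ_j|

via L-BFGS-B on the positive/negative split of λ (the L1 term becomes
linear, keeping the objective smooth and the gradient exact); β defaults to
0.05 per feature class.  At the optimum the regularised moment condition
|E_presence[f] − E_model[f]| ≤ β holds elementwise (tested).  Prediction:
log p(x|bin) = λ·f(x) − log Z over the shared background measure; the
posterior over bins uses training bin proportions as priors; pixel mean is
the posterior-weighted bin center and pixel variance adds the posterior
expectation of within-bin variance (toggleable).  Background defaults to a
seeded subsample (≤50,000) of forest pixels.  Pixels with any nodata
covariate are nodata in every output.

## Uncertainty framework

* **Cross-validation.**  Plot-wise CV: random sample-level folds.
  Latitudinal CV: contiguous equal-count quantile bands of sample latitude,
  training on all other bands.  Both retrain the full binning + MaxEnt
  pipeline per fold (bin count adapts to fold size, `min(n_bins,
  n_train/10)`, so small folds stay fittable).  Under long-range residual
  autocorrelation the blocked scheme is farther from its training data and
  its RMSE stochastically dominates the random scheme; with iid residuals
  the two agree — both behaviours are tested.
* **Semivariograms.**  γ(h) = mean of ½(vᵢ−vⱼ)² per lag bin; all pairs when
  ≤ `max_pairs` (default 10⁶), else a seeded pair subsample.  Fitting is
  least squares weighted by √(pair count) with nugget clipped at 0; a pure
  nugget fit (white noise) is flagged.  The first lag bin should start
  just above 0 and be narrow when the nugget is the quantity of interest —
  the nugget is an extrapolation to zero lag and wide first bins bias it.
* **Covariance ratio.**  residual partial sill / map partial sill — the
  fraction of spatially structured variance the mapping failed to remove.
* **Quadrature.**  Independent error sds combine as √Σc²; the ErrorBudget
  container asserts this identity.
* **Regional inference.**  se² = (1/n²)·sᵀRs with R the variogram-implied
  correlation matrix (negative correlations clipped at 0), evaluated
  densely up to 10⁴ pixels; larger regions use the effective-sample-size
  approximation n_eff = n/(1 + (n−1)ρ̄) with ρ̄ from a seeded pair
  subsample.  The dense quadratic form is the oracle the approximation is
  validated against.  The iid and perfect-correlation limits (s/√n and s)
  bound the result.

## Carbon accounting

BGB = 0.489·AGB^0.89 (a standard concave root:shoot allometry; coefficients
are configuration), carbon = 0.49·(AGB + BGB), both applied pixelwise.
Because the allometry is concave, carbon computed pixelwise then averaged
is *not* the same as applying the allometry to the regional mean AGB —
the package computes pixel-level only and documents the discrepancy rather
than reconciling the two.  Totals follow Mg ha⁻¹ × Mha × 10⁶ × 10⁻⁹ = Pg;
region tables report means to 2 decimals and totals to 3.  Region rows
without forest pixels are emitted with zero area and flagged, never
dropped.

## Environmental controls

Upscaling is the same block-mean (with valid-fraction threshold) as MCH
aggregation.  Variable importance is forward-stepwise OLS on standardized
variables maximising adjusted R² per step — chosen as the simplest
transparent reading of "ranked variables with cumulative variance
explained"; collinear late additions contribute ~0 and are flagged.
Binned response curves use equal-width bins over the variable's observed
range with a per-bin bootstrap (default 500 resamples) for the se of the
bin mean; empty bins are omitted with a flag.

## Problem sizes and determinism

Experiments are sized for a desk machine: recovery experiments use 92-plot
replicates (×200), variogram recovery 200×200 fields with ~6000-point
subsamples (×10), CV calibration 20 meta-replicates of 200 splits, coverage
500 designs of 25 clusters, and the end-to-end narrative a 300×300-cell
landscape.  Every stochastic routine takes an explicit seed; fixed seeds
give bit-identical rasters and tables, and the acceptance script derives
all of its generators from a single `--seed` via `SeedSequence` spawning.

## Known limitations

* The plot observation model (additive, truncated at zero) conflicts mildly
  with the multiplicative fit; at low AGB this inflates and skews log
  residuals, which is visible in the worked example as an exponent estimate
  above the generating value and a negative MSD.  This is a faithful
  rendering of a real misspecification, not a defect to calibrate away.
* Kriging is per-target local with a dense solve; it is meant for gap
  filling at fine resolution, not for kriging whole scenes.
* The MaxEnt estimator's bin count, feature classes and β are declared
  defaults of this implementation; no claim is made that they match any
  particular published MaxEnt configuration.
* Geodesy is a fixed equal-area approximation (111.32 km/degree); no true
  graticule geometry, datum or reprojection is implemented.
* Variance-explained statistics from stepwise OLS are descriptive rankings,
  not causal attributions.
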