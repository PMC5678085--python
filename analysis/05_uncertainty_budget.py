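#!/usr/bin/env python
"""Assemble the uncertainty budget of the biomass map.

Runs the two cross-validation schemes (random plot-wise folds and contiguous
latitude-band folds) over the MaxEnt pipeline, fits semivariograms to the
map and to its residuals (residual nugget = geolocation-error proxy,
partial-sill ratio = retained structured variance), and combines the
independent error components in quadrature.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from forestcarbon.raster import read_raster
from forestcarbon.uncertainty import (
    covariance_ratio,
    cv_latitudinal,
    cv_plotwise,
    empirical_semivariogram,
    fit_variogram,
    propagate_errors,
)

RUN = Path(__file__).resolve().parents[1] / "results" / "run"
COVARIATES = ["optical", "radar", "terrain"]


def main(seed: int = 5) -> None:
    train = pd.read_csv(RUN / "maxent_training.csv")
    model_cv = json.loads((RUN / "model_cv.json").read_text())
    rng = np.random.default_rng(seed)
    covs = [read_raster(RUN / f"cov_{n}.tif") for n in COVARIATES]
    mask = read_raster(RUN / "forest_mask.tif")
    forest = mask.valid_mask() & (mask.values > 0)
    bg_idx = rng.choice(np.nonzero(forest.ravel())[0], size=5000, replace=False)
    background = np.column_stack([c.values.ravel()[bg_idx] for c in covs])

    sub = train.sample(n=min(len(train), 800), random_state=seed)
    cvp = cv_plotwise(sub, COVARIATES, background, k_folds=5, n_bins=10, seed=seed)
    cvl = cv_latitudinal(sub, COVARIATES, background, n_bands=5, n_bins=10,
                         seed=seed)

    scatter = pd.read_csv(RUN / "map_evaluation.csv")
    max_lag = 15_000.0
    lags = np.linspace(0, max_lag, 16)
    map_pts = scatter.rename(columns={"observed": "value"})[["x", "y", "value"]]
    res_pts = scatter.assign(value=scatter["predicted"] - scatter["observed"])
    emp_map = empirical_semivariogram(map_pts, lags, max_pairs=400_000, seed=seed)
    emp_res = empirical_semivariogram(res_pts, lags, max_pairs=400_000, seed=seed)
    vg_map = fit_variogram(emp_map)
    vg_res = fit_variogram(emp_res)
    ratio = covariance_ratio(vg_map, vg_res)
    nugget_sd = float(np.sqrt(vg_res.nugget))

    combined = propagate_errors([model_cv["cv_rmse"], nugget_sd, cvp["rmse"]])
    budget = {
        "cv_plotwise": cvp,
        "cv_latitudinal": cvl,
        "model_rmse": model_cv["cv_rmse"],
        "residual_nugget_sd": nugget_sd,
        "map_variogram": vars(vg_map),
        "residual_variogram": vars(vg_res),
        "residual_partial_sill_ratio": ratio,
        "combined_error": combined,
    }
    (RUN / "error_budget.json").write_text(json.dumps(budget, indent=2))
    print(f"plot-wise CV RMSE = {cvp['rmse']:.1f} +- {cvp['rmse_sd']:.1f}; "
          f"latitudinal CV RMSE = {cvl['rmse']:.1f} +- {cvl['rmse_sd']:.1f}")
    print(f"residual nugget sd = {nugget_sd:.1f} Mg/ha; "
          f"residual/map partial-sill ratio = {ratio:.2f}")
    print(f"combined error (model, geolocation, mapping in quadrature) = "
          f"{combined:.1f} Mg/ha")


if __name__ == "__main__":
    main()
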