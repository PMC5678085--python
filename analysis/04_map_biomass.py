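#!/usr/bin/env python
"""Extrapolate transect biomass to a wall-to-wall map with the MaxEnt
estimator.

Applies the fitted power law to the LiDAR-observed (here: true) height and
wood density inside transects to obtain training biomass, bins it, fits the
per-bin penalised maximum-entropy densities over the covariates, and
predicts pixel mean and sd everywhere.  Reports RMSE/MSD against the
training pixels.
"""

import json
from pathlib import Path

import numpy as np

from forestcarbon.agb import PowerLawModel, predict_agb
from forestcarbon.maxent import (
    bin_training_samples,
    fit_maxent_models,
    map_evaluation,
    predict_map,
    save_models,
)
from forestcarbon.raster import read_raster, write_raster
from forestcarbon.sampling import TransectSet, extract_transect_samples

RUN = Path(__file__).resolve().parents[1] / "results" / "run"
COVARIATES = ["optical", "radar", "terrain"]


def main(seed: int = 4) -> None:
    rng = np.random.default_rng(seed)
    wd = read_raster(RUN / "wood_density.tif")
    height = read_raster(RUN / "height.tif")
    mask = read_raster(RUN / "forest_mask.tif")
    covs = [read_raster(RUN / f"cov_{n}.tif") for n in COVARIATES]
    model = PowerLawModel.from_json(RUN / "power_law.json")
    transects = TransectSet.from_geojson(RUN / "transects.geojson")

    lidar_agb = predict_agb(model, wd, height)
    train = extract_transect_samples(lidar_agb, transects)
    train = train.sample(n=min(len(train), 3000), random_state=seed)
    for name, cov in zip(COVARIATES, covs):
        train[name] = cov.value_at(train["x"].to_numpy(), train["y"].to_numpy())
    train = train.rename(columns={"value": "agb"})
    train.to_csv(RUN / "maxent_training.csv", index=False)

    forest = mask.valid_mask() & (mask.values > 0)
    bg_idx = rng.choice(np.nonzero(forest.ravel())[0],
                        size=min(int(forest.sum()), 20_000), replace=False)
    background = np.column_stack([c.values.ravel()[bg_idx] for c in covs])

    binning, labeled = bin_training_samples(train, n_bins=15)
    models = fit_maxent_models(labeled, binning, COVARIATES, background,
                               beta=0.05)
    priors = np.bincount(labeled["bin_id"], minlength=binning.n_bins) / len(labeled)
    agb_map = predict_map(models, binning, covs, priors)
    write_raster(agb_map.mean, RUN / "agb_mean.tif")
    write_raster(agb_map.sd, RUN / "agb_sd.tif")
    save_models(models, binning, RUN / "maxent_models.json")

    rmse, msd, scatter = map_evaluation(agb_map, train[["x", "y", "agb"]])
    scatter.to_csv(RUN / "map_evaluation.csv", index=False)
    (RUN / "map_metrics.json").write_text(
        json.dumps({"rmse": rmse, "msd": msd, "n_training": len(train)}, indent=2)
    )
    print(f"mapped {int((agb_map.mean.values != agb_map.mean.nodata).sum())} pixels")
    print(f"map vs training samples: RMSE = {rmse:.1f} Mg/ha, MSD = {msd:+.2f} Mg/ha")


if __name__ == "__main__":
    main()
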