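"""Pipeline configuration and the end-to-end orchestrator.

The configuration is a flat ``key = value`` text file; unknown keys are
rejected so that typos cannot silently fall back to defaults.  The
orchestrator runs simulate -> design -> lidar metrics -> fit -> map ->
uncertainty -> carbon report -> environment report, writing every artifact
plus a manifest (config hash, seeds, package version) into the run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import __version__
from .agb import bootstrap_cv, fit_power_law, predict_agb
from .carbon import CarbonConfig, bgb_from_agb, carbon_density, region_table
from .envcontrols import binned_means, upscale, variable_importance
from .lidar import aggregate_mch, forest_mask_from_mch
from .maxent import (
    AGBMap,
    bin_training_samples,
    fit_maxent_models,
    map_evaluation,
    predict_map,
    save_models,
)
from .raster import write_raster
from .sampling import cluster_mean_variance, design_transects, extract_transect_samples
from .synthetic import LandscapeConfig, generate_true_state, simulate_ground_plots
from .uncertainty import (
    cv_latitudinal,
    cv_plotwise,
    empirical_semivariogram,
    fit_variogram,
    propagate_errors,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run; seeds are always explicit."""

    # landscape
    extent_rows: int = 200
    extent_cols: int = 200
    cell_size_m: float = 100.0
    height_min_m: float = 0.0
    height_max_m: float = 60.0
    spatial_range_m: float = 3000.0
    sill: float = 25.0
    nugget: float = 1.0
    agb_noise_cv: float = 0.2
    landscape_seed: int = 1
    # design
    grid_deg: float = 0.05
    per_cell: int = 1
    target_area_ha: float = 200.0
    aspect_ratio: float = 8.89
    design_seed: int = 2
    # plots
    n_plots: int = 92
    plot_noise_sd: float = 52.0
    plot_transect_fraction: float = 0.15
    plot_seed: int = 3
    # mapping
    n_bins: int = 12
    beta: float = 0.05
    map_seed: int = 4
    # lidar metrics / mask
    min_height_m: float = 3.0
    # carbon
    carbon_fraction: float = 0.49
    bgb_coeff: float = 0.489
    bgb_exp: float = 0.89
    # uncertainty
    k_folds: int = 5
    n_bands: int = 5
    cv_seed: int = 5
    n_boot: int = 200
    # environment analysis
    env_upscale_factor: int = 5
    env_n_bins: int = 8
    env_n_boot: int = 200
    env_seed: int = 6

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            typ = known[key]
            kwargs[key] = int(val) if typ == "int" else float(val)
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full chain on a synthetic landscape; returns the run dir.

    A stage failure aborts with the stage name; artifacts written so far are
    left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": [],
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("simulate")
        lc = LandscapeConfig(
            extent_cells=(config.extent_rows, config.extent_cols),
            cell_size_m=config.cell_size_m,
            height_range_m=(config.height_min_m, config.height_max_m),
            spatial_range_m=config.spatial_range_m,
            sill=config.sill,
            nugget=config.nugget,
            agb_noise_cv=config.agb_noise_cv,
            seed=config.landscape_seed,
        )
        state = generate_true_state(lc)
        write_raster(state.height, out / "height.tif")
        write_raster(state.wood_density, out / "wood_density.tif")
        write_raster(state.agb_true, out / "agb_true.tif")
        for name, cov in zip(state.covariate_names, state.covariates):
            write_raster(cov, out / f"cov_{name}.tif")

        stage("lidar_metrics")
        mask, area_mha = forest_mask_from_mch(state.height, config.min_height_m)
        write_raster(mask, out / "forest_mask.tif")

        stage("design")
        transects = design_transects(
            mask, grid_deg=config.grid_deg, per_cell=config.per_cell,
            target_area_ha=config.target_area_ha,
            aspect_ratio=config.aspect_ratio, seed=config.design_seed,
        )
        transects.to_geojson(out / "transects.geojson")
        samples = extract_transect_samples(state.agb_true, transects)
        samples.to_csv(out / "transect_samples.csv", index=False)
        est = cluster_mean_variance(samples)
        (out / "design_estimate.json").write_text(json.dumps(asdict(est)))

        stage("fit")
        plots = simulate_ground_plots(
            state, transects, n_plots=config.n_plots,
            obs_noise_sd=config.plot_noise_sd,
            transect_fraction=config.plot_transect_fraction,
            seed=config.plot_seed,
        )
        plots.to_csv(out / "ground_plots.csv", index=False)
        model = fit_power_law(plots)
        model.to_json(out / "power_law.json")
        cv = bootstrap_cv(plots, n_boot=config.n_boot, seed=config.plot_seed)

        stage("map")
        rng = np.random.default_rng(config.map_seed)
        lidar_agb = predict_agb(model, state.wood_density, state.height)
        train_samples = extract_transect_samples(lidar_agb, transects)
        n_train = min(len(train_samples), 2000)
        train = train_samples.sample(n=n_train, random_state=config.map_seed)
        cov_cols = state.covariate_names
        for name, cov in zip(cov_cols, state.covariates):
            train[name] = cov.value_at(train["x"].to_numpy(), train["y"].to_numpy())
        train = train.rename(columns={"value": "agb"})
        forest = mask.valid_mask() & (mask.values > 0)
        bg_idx = np.nonzero(forest.ravel())[0]
        bg_idx = rng.choice(bg_idx, size=min(len(bg_idx), 5000), replace=False)
        background = np.column_stack(
            [c.values.ravel()[bg_idx].astype(float) for c in state.covariates]
        )
        binning, labeled = bin_training_samples(train, n_bins=config.n_bins)
        models = fit_maxent_models(labeled, binning, cov_cols, background,
                                   beta=config.beta)
        priors = np.bincount(labeled["bin_id"], minlength=binning.n_bins).astype(float)
        priors /= priors.sum()
        agb_map = predict_map(models, binning, state.covariates, priors)
        write_raster(agb_map.mean, out / "agb_mean.tif")
        write_raster(agb_map.sd, out / "agb_sd.tif")
        save_models(models, binning, out / "maxent_models.json")
        ref = train[["x", "y", "agb"]]
        rmse, msd, scatter = map_evaluation(agb_map, ref)
        scatter.to_csv(out / "map_evaluation.csv", index=False)

        stage("uncertainty")
        cvp = cv_plotwise(train, cov_cols, background, k_folds=config.k_folds,
                          n_bins=config.n_bins, beta=config.beta,
                          seed=config.cv_seed)
        cvl = cv_latitudinal(train, cov_cols, background, n_bands=config.n_bands,
                             n_bins=config.n_bins, beta=config.beta,
                             seed=config.cv_seed)
        resid_pts = scatter.assign(value=scatter["predicted"] - scatter["observed"])
        max_lag = 0.5 * config.extent_cols * config.cell_size_m
        emp = empirical_semivariogram(
            resid_pts, np.linspace(0, max_lag, 13), seed=config.cv_seed
        )
        emp.to_csv(out / "residual_semivariogram.csv", index=False)
        try:
            vg = fit_variogram(emp)
            nugget_sd = float(np.sqrt(vg.nugget))
        except Exception as exc:  # degenerate variograms stay diagnostic
            log.warning("residual variogram fit failed: %s", exc)
            vg, nugget_sd = None, float("nan")
        budget = {
            "model_error": cv["rmse"],
            "geolocation_error": nugget_sd,
            "mapping_error": cvp["rmse"],
            "combined": propagate_errors(
                [cv["rmse"], 0.0 if np.isnan(nugget_sd) else nugget_sd, cvp["rmse"]]
            ),
            "cv_plotwise": cvp,
            "cv_latitudinal": cvl,
            "map_rmse": rmse,
            "map_msd": msd,
        }
        (out / "error_budget.json").write_text(json.dumps(budget, indent=2))

        stage("carbon_report")
        cconf = CarbonConfig(config.carbon_fraction, config.bgb_coeff, config.bgb_exp)
        bgb = bgb_from_agb(agb_map.mean, cconf)
        carbon = carbon_density(agb_map.mean, bgb, cconf)
        write_raster(carbon, out / "carbon.tif")
        carbon_sd = carbon.like(
            np.where(agb_map.sd.valid_mask(),
                     config.carbon_fraction * agb_map.sd.values, carbon.nodata)
        )
        xmin, ymin, xmax, ymax = mask.bounds
        xmid = 0.5 * (xmin + xmax)
        regions = [
            ("west", box(xmin, ymin, xmid, ymax)),
            ("east", box(xmid, ymin, xmax, ymax)),
        ]
        table = region_table(agb_map, carbon, carbon_sd, regions, [mask],
                             variogram=vg, mask_names=("FA1",))
        table.to_csv(out / "region_table.csv", index=False)

        stage("env_report")
        coarse_c = upscale(carbon, factor=config.env_upscale_factor)
        env_stack = {
            name: upscale(cov, factor=config.env_upscale_factor)
            for name, cov in zip(cov_cols, state.covariates)
        }
        imp = variable_importance(coarse_c, env_stack, max_vars=len(env_stack))
        imp.to_csv(out / "variable_importance.csv", index=False)
        for name, layer in env_stack.items():
            br = binned_means(coarse_c, layer, variable_name=name,
                              n_bins=config.env_n_bins, n_boot=config.env_n_boot,
                              seed=config.env_seed)
            br.to_frame().to_csv(out / f"binned_{name}.csv", index=False)
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
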