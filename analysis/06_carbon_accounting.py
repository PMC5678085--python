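#!/usr/bin/env python
"""Convert the biomass map to total live carbon and produce the
jurisdictional statistics table.

BGB = 0.489 AGB^0.89 pixelwise, carbon = 0.49 (AGB + BGB); the landscape is
split into four quadrant "provinces" and per-region forest area, mean +- se
and totals are tabulated, with the union "All" row.
"""

import json
from pathlib import Path

import numpy as np
from shapely.geometry import box

from forestcarbon.carbon import CarbonConfig, bgb_from_agb, carbon_density, region_table
from forestcarbon.lidar import VariogramModel
from forestcarbon.maxent import AGBMap
from forestcarbon.raster import read_raster, write_raster

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    mean = read_raster(RUN / "agb_mean.tif")
    sd = read_raster(RUN / "agb_sd.tif")
    mask = read_raster(RUN / "forest_mask.tif")
    cfg = CarbonConfig()
    bgb = bgb_from_agb(mean, cfg)
    carbon = carbon_density(mean, bgb, cfg)
    write_raster(carbon, RUN / "carbon.tif")
    carbon_sd = carbon.like(
        np.where(sd.valid_mask(), cfg.carbon_fraction * sd.values, carbon.nodata)
    )

    budget = json.loads((RUN / "error_budget.json").read_text())
    vg = VariogramModel(**budget["residual_variogram"])

    xmin, ymin, xmax, ymax = mask.bounds
    xm, ym = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    regions = [
        ("northwest", box(xmin, ym, xm, ymax)),
        ("northeast", box(xm, ym, xmax, ymax)),
        ("southwest", box(xmin, ymin, xm, ym)),
        ("southeast", box(xm, ymin, xmax, ym)),
    ]
    amap = AGBMap(mean=mean, sd=sd)
    table = region_table(amap, carbon, carbon_sd, regions, [mask],
                         variogram=vg, mask_names=("FA1",))
    table.to_csv(RUN / "region_table.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
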