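"""Carbon accounting: belowground allometry, carbon fraction, and
jurisdictional (province-style) statistics tables.

Total live carbon per hectare is 0.49 * (AGB + BGB), with belowground biomass
from the concave root:shoot allometry BGB = 0.489 * AGB^0.89 applied
pixelwise.  Jurisdictional totals follow the unit chain
Mg ha^-1 x Mha x 10^6 ha/Mha x 10^-9 Pg/Mg = Pg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .lidar import VariogramModel
from .maxent import AGBMap
from .raster import RasterGrid, require_aligned
from .uncertainty import regional_inference

log = logging.getLogger(__name__)

#: Unit-chain constants: hectares per Mha, Pg per Mg.
HA_PER_MHA = 1e6
PG_PER_MG = 1e-9


@dataclass
class CarbonConfig:
    carbon_fraction: float = 0.49
    bgb_coeff: float = 0.489
    bgb_exp: float = 0.89

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError("carbon_fraction must be in (0, 1)")
        if self.bgb_coeff <= 0 or not 0.0 < self.bgb_exp <= 1.0:
            raise ValueError("require bgb_coeff > 0 and 0 < bgb_exp <= 1")


def bgb_from_agb(agb: RasterGrid, config: CarbonConfig | None = None) -> RasterGrid:
    """Belowground biomass bgb = coeff * agb^exp, cellwise; 0 at 0."""
    config = config or CarbonConfig()
    valid = agb.valid_mask()
    if (agb.values[valid] < 0).any():
        raise ValueError("negative AGB")
    out = np.full(agb.shape, agb.nodata, dtype=float)
    out[valid] = config.bgb_coeff * np.power(agb.values[valid], config.bgb_exp)
    return agb.like(out)


def carbon_density(
    agb: RasterGrid, bgb: RasterGrid, config: CarbonConfig | None = None
) -> RasterGrid:
    """Total live carbon density = carbon_fraction * (AGB + BGB), cellwise."""
    config = config or CarbonConfig()
    require_aligned(agb, bgb)
    valid = agb.valid_mask() & bgb.valid_mask()
    out = np.full(agb.shape, agb.nodata, dtype=float)
    out[valid] = config.carbon_fraction * (agb.values[valid] + bgb.values[valid])
    return agb.like(out)


def total_pg(mean_mg_ha: float, area_mha: float) -> float:
    """Total stock in Pg from a mean density (Mg ha^-1) and an area (Mha)."""
    return mean_mg_ha * area_mha * HA_PER_MHA * PG_PER_MG


def region_table(
    agb_map: AGBMap,
    carbon: RasterGrid,
    carbon_sd: RasterGrid,
    regions: list[tuple[str, "shapely.Geometry"]],
    forest_masks: list[RasterGrid],
    variogram: VariogramModel | None = None,
    mask_names: tuple[str, ...] = ("FA1", "FA2"),
) -> pd.DataFrame:
    """Jurisdictional statistics table: per region and an "All" union row.

    The first forest mask defines the pixels entering means and totals; the
    areas of all masks are reported as FA columns.  Means carry model-based
    standard errors from :func:`regional_inference`; totals are mean x area
    with the se scaled by the same area.  Regions without forest pixels yield
    a flagged row with zero area and NaN statistics.
    """
    primary = forest_masks[0]
    require_aligned(agb_map.mean, agb_map.sd, carbon, carbon_sd, primary)
    cell_ha = (primary.cell_size**2) / 1e4
    gx, gy = primary.center_grids()

    rows = []
    union_mask = np.zeros(primary.shape, dtype=bool)
    for region_id, geom in regions:
        inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(primary.shape)
        fas = []
        for m in forest_masks:
            sel = inside & m.valid_mask() & (m.values > 0)
            fas.append(sel.sum() * cell_ha / HA_PER_MHA)
        sel = inside & primary.valid_mask() & (primary.values > 0)
        union_mask |= sel
        rows.append(_region_row(region_id, sel, fas, agb_map, carbon, carbon_sd,
                                variogram, mask_names))
    fas_all = [
        (m.valid_mask() & (m.values > 0)).sum() * cell_ha / HA_PER_MHA
        for m in forest_masks
    ]
    rows.append(_region_row("All", union_mask, fas_all, agb_map, carbon, carbon_sd,
                            variogram, mask_names))
    return pd.DataFrame(rows)


def _region_row(region_id, sel, fas, agb_map, carbon, carbon_sd, variogram,
                mask_names):
    row = {"region_id": region_id}
    for name, fa in zip(mask_names, fas):
        row[f"{name.lower()}_mha"] = round(float(fa), 4)
    fa1 = fas[0]
    if not sel.any():
        log.warning("region %s holds no forest pixels", region_id)
        row.update(
            agb_mean=np.nan, agb_se=np.nan, carbon_mean=np.nan, carbon_se=np.nan,
            agb_total_pg=np.nan, agb_total_se_pg=np.nan,
            carbon_total_pg=np.nan, carbon_total_se_pg=np.nan, flagged=True,
        )
        return row
    agb_mean, agb_se, _ = regional_inference(agb_map.mean, agb_map.sd, sel, variogram)
    c_mean, c_se, _ = regional_inference(carbon, carbon_sd, sel, variogram)
    row.update(
        agb_mean=round(agb_mean, 2),
        agb_se=round(agb_se, 2),
        carbon_mean=round(c_mean, 2),
        carbon_se=round(c_se, 2),
        agb_total_pg=round(total_pg(agb_mean, fa1), 3),
        agb_total_se_pg=round(total_pg(agb_se, fa1), 3),
        carbon_total_pg=round(total_pg(c_mean, fa1), 3),
        carbon_total_se_pg=round(total_pg(c_se, fa1), 3),
        flagged=False,
    )
    return row
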