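import numpy as np
import pandas as pd
import pytest

from forestcarbon.raster import RasterGrid
from forestcarbon.sampling import TransectSet, TransectSpec, _transect_polygon
from forestcarbon.synthetic import LandscapeConfig, generate_true_state


@pytest.fixture(scope="session")
def small_state():
    """A 60x60-cell noise-free landscape shared by read-only tests."""
    cfg = LandscapeConfig(
        extent_cells=(60, 60), cell_size_m=100.0, spatial_range_m=1500.0,
        sill=16.0, nugget=0.5, agb_noise_cv=0.0, seed=42,
    )
    return generate_true_state(cfg)


@pytest.fixture()
def flat_raster():
    return RasterGrid(np.full((20, 20), 30.0), x0=0.0, y0=2000.0, cell_size=100.0)


def make_transect_set(origin, heading_deg, width_m, length_m):
    poly = _transect_polygon(origin, heading_deg, width_m, length_m)
    spec = TransectSpec(origin=origin, heading_deg=heading_deg, width_m=width_m,
                        length_m=length_m, grid_cell_id="cell_0_0", seed=0)
    return TransectSet(specs=[spec], polygons=[poly])


def synthetic_plots(rng, n=92, noise="lognormal", sd=52.0, cv=0.2,
                    a=10.43, b=1.19):
    """Ground plots drawn from the power-law forward model.

    MCH ~ U(10, 45) m, WD ~ N(0.66, 0.05) truncated to (0.3, 1.0);
    noise is multiplicative lognormal (log-mean 0) or additive Gaussian
    truncated at zero.
    """
    mch = rng.uniform(10.0, 45.0, n)
    wd = np.clip(rng.normal(0.66, 0.05, n), 0.3, 1.0)
    agb = a * (wd * mch) ** b
    if noise == "lognormal" and cv > 0:
        agb = agb * rng.lognormal(0.0, np.sqrt(np.log1p(cv**2)), n)
    elif noise == "additive" and sd > 0:
        agb = np.maximum(agb + rng.normal(0.0, sd, n), 0.0)
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(n)],
            "x": rng.uniform(0, 1e5, n),
            "y": rng.uniform(0, 1e5, n),
            "agb_obs": agb,
            "wd_mean": wd,
            "mch": mch,
        }
    )
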