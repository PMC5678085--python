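import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestcarbon.lidar import VariogramModel
from forestcarbon.raster import RasterGrid
from forestcarbon.synthetic import exponential_field
from forestcarbon.uncertainty import (
    ErrorBudget,
    UncertaintyError,
    covariance_ratio,
    cv_latitudinal,
    cv_plotwise,
    empirical_semivariogram,
    fit_variogram,
    propagate_errors,
    regional_inference,
)


class TestPropagate:
    def test_printed_component_quadrature(self):
        """Combining model (~50), geolocation (~50) and mapping (~70)
        error sds gives ~99.5, i.e. about 100."""
        assert propagate_errors([50.0, 50.0, 70.0]) == pytest.approx(99.5, abs=0.05)

    def test_single_component_passthrough(self):
        assert propagate_errors([13.7]) == 13.7

    def test_pythagorean(self):
        assert propagate_errors([3.0, 4.0]) == pytest.approx(5.0)

    def test_empty_and_negative_rejected(self):
        with pytest.raises(UncertaintyError):
            propagate_errors([])
        with pytest.raises(UncertaintyError):
            propagate_errors([1.0, -2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e3), min_size=1, max_size=6))
    def test_exceeds_each_component(self, comps):
        c = propagate_errors(comps)
        assert all(c >= x - 1e-9 for x in comps)

    def test_error_budget_invariant(self):
        b = ErrorBudget(model_error=52.0, geolocation_error=50.0, mapping_error=61.0)
        assert b.combined == pytest.approx(
            np.sqrt(52.0**2 + 50.0**2 + 61.0**2), abs=1e-9
        )


class TestSemivariogram:
    def test_constant_field_zero_gamma(self):
        pts = pd.DataFrame({"x": np.arange(30.0), "y": 0.0, "value": 5.0})
        emp = empirical_semivariogram(pts, np.array([0.0, 5.0, 10.0, 40.0]))
        assert (emp.dropna()["gamma"] == 0.0).all()

    def test_white_noise_flat_at_sigma_squared(self):
        rng = np.random.default_rng(0)
        n = 800
        pts = pd.DataFrame({"x": rng.uniform(0, 100, n),
                            "y": rng.uniform(0, 100, n),
                            "value": rng.normal(0, 3.0, n)})
        emp = empirical_semivariogram(pts, np.linspace(0, 80, 9))
        good = emp[emp["n_pairs"] > 1e4]
        assert np.allclose(good["gamma"], 9.0, rtol=0.1)

    def test_four_point_hand_computation(self):
        """All six pairs of a 4-point configuration, binned and averaged by
        hand."""
        pts = pd.DataFrame({"x": [0.0, 1.0, 0.0, 3.0],
                            "y": [0.0, 0.0, 2.0, 0.0],
                            "value": [1.0, 3.0, 2.0, 7.0]})
        # pairs: (0,1) d=1 dv=4 | (0,2) d=2 dv=1 | (0,3) d=3 dv=36
        #        (1,2) d=sqrt5 dv=1 | (1,3) d=2 dv=16 | (2,3) d=sqrt13 dv=25
        emp = empirical_semivariogram(pts, np.array([0.0, 1.5, 2.5, 4.0]))
        assert emp["n_pairs"].tolist() == [1, 3, 2]
        assert emp["gamma"][0] == pytest.approx(0.5 * 4.0)
        assert emp["gamma"][1] == pytest.approx(0.5 * (1 + 1 + 16) / 3)
        assert emp["gamma"][2] == pytest.approx(0.5 * (36 + 25) / 2)

    def test_pair_subsampling_is_seeded(self):
        rng = np.random.default_rng(1)
        n = 600
        pts = pd.DataFrame({"x": rng.uniform(0, 100, n),
                            "y": rng.uniform(0, 100, n),
                            "value": rng.normal(size=n)})
        e1 = empirical_semivariogram(pts, np.linspace(0, 50, 6),
                                     max_pairs=5000, seed=9)
        e2 = empirical_semivariogram(pts, np.linspace(0, 50, 6),
                                     max_pairs=5000, seed=9)
        pd.testing.assert_frame_equal(e1, e2)


class TestFitVariogram:
    def test_exact_model_round_trip(self):
        vg = VariogramModel("exponential", nugget=2.0, sill=12.0, range_m=800.0)
        lags = np.linspace(20, 2000, 25)
        emp = pd.DataFrame({"lag": lags, "gamma": vg.gamma(lags),
                            "n_pairs": 1000})
        fit = fit_variogram(emp)
        assert fit.nugget == pytest.approx(2.0, abs=1e-3 * 12)
        assert fit.sill == pytest.approx(12.0, rel=1e-3)
        assert fit.range_m == pytest.approx(800.0, rel=1e-2)

    def test_white_noise_flags_pure_nugget(self, caplog):
        emp = pd.DataFrame({"lag": np.linspace(5, 100, 10),
                            "gamma": 4.0, "n_pairs": 500})
        with caplog.at_level("WARNING"):
            fit = fit_variogram(emp)
        assert fit.nugget == pytest.approx(fit.sill, rel=1e-6)

    def test_too_few_lags_rejected(self):
        emp = pd.DataFrame({"lag": [1.0, 2.0, 3.0], "gamma": 1.0, "n_pairs": 10})
        with pytest.raises(UncertaintyError):
            fit_variogram(emp)

    def test_nugget_sd_recovery_from_simulated_field(self):
        """Smooth field + iid noise of sd 50: the fitted sqrt(nugget)
        recovers 50 within 15% over replicates."""
        roots = []
        for s in range(6):
            rng = np.random.default_rng(s)
            f = exponential_field((150, 150), 1.0, 30.0, 70.0**2, rng)
            f = f + rng.normal(0, 50.0, f.shape)
            gx, gy = np.meshgrid(np.arange(150.0), np.arange(150.0))
            idx = rng.choice(f.size, 5000, replace=False)
            pts = pd.DataFrame({"x": gx.ravel()[idx], "y": gy.ravel()[idx],
                                "value": f.ravel()[idx]})
            edges = np.concatenate([[0.5], np.linspace(1.5, 70, 20)])
            emp = empirical_semivariogram(pts, edges, max_pairs=300_000, seed=s)
            roots.append(np.sqrt(fit_variogram(emp).nugget))
        assert np.mean(roots) == pytest.approx(50.0, rel=0.15)


class TestCovarianceRatio:
    def test_identical_variograms_ratio_one(self):
        vg = VariogramModel("exponential", nugget=1.0, sill=10.0, range_m=100.0)
        assert covariance_ratio(vg, vg) == 1.0

    def test_printed_partial_sills(self):
        """Residual structured variance 3000 against map 15000 gives 0.2."""
        vmap = VariogramModel("exponential", nugget=0.0, sill=15000.0,
                              range_m=200_000.0)
        vres = VariogramModel("exponential", nugget=0.0, sill=3000.0,
                              range_m=200_000.0)
        assert covariance_ratio(vmap, vres) == pytest.approx(0.2)

    def test_nugget_only_residual_ratio_zero(self):
        vmap = VariogramModel("exponential", nugget=0.0, sill=100.0, range_m=50.0)
        vres = VariogramModel("exponential", nugget=5.0, sill=5.0, range_m=50.0)
        assert covariance_ratio(vmap, vres) == 0.0

    def test_zero_map_partial_sill_rejected(self):
        flat = VariogramModel("exponential", nugget=3.0, sill=3.0, range_m=50.0)
        with pytest.raises(UncertaintyError):
            covariance_ratio(flat, flat)


class TestRegionalInference:
    def make_maps(self, n=10, sd=4.0):
        mean = RasterGrid(np.full((n, n), 100.0), x0=0, y0=n * 100.0,
                          cell_size=100.0)
        sd_map = mean.like(np.full((n, n), sd))
        return mean, sd_map

    def test_iid_limit(self):
        mean, sd = self.make_maps(n=10, sd=4.0)
        _, se, rel = regional_inference(mean, sd, np.ones((10, 10), dtype=bool))
        assert se == pytest.approx(4.0 / 10.0)
        assert rel == pytest.approx(100 * se / 100.0)

    def test_perfect_correlation_limit(self):
        mean, sd = self.make_maps(n=8, sd=4.0)
        vg = VariogramModel("exponential", nugget=0.0, sill=10.0, range_m=1e12)
        _, se, _ = regional_inference(mean, sd, np.ones((8, 8), dtype=bool), vg)
        assert se == pytest.approx(4.0, rel=1e-3)

    def test_dense_quadratic_form_oracle(self):
        """100-pixel region with an explicit correlation matrix: se matches
        the direct quadratic-form computation."""
        rng = np.random.default_rng(3)
        mean = RasterGrid(rng.uniform(50, 150, (10, 10)), x0=0, y0=1000,
                          cell_size=100.0)
        sd = mean.like(rng.uniform(2, 8, (10, 10)))
        vg = VariogramModel("exponential", nugget=1.0, sill=5.0, range_m=600.0)
        region = np.ones((10, 10), dtype=bool)
        m, se, _ = regional_inference(mean, sd, region, vg)
        gx, gy = mean.center_grids()
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        rho = np.maximum(vg.correlation(d), 0.0)
        np.fill_diagonal(rho, 1.0)
        s = sd.values.ravel()
        se_direct = np.sqrt(s @ (rho @ s)) / 100
        assert se == pytest.approx(se_direct, rel=1e-9)
        assert m == pytest.approx(mean.values.mean())

    def test_se_bounded_between_iid_and_max(self):
        rng = np.random.default_rng(4)
        mean = RasterGrid(np.full((12, 12), 80.0), x0=0, y0=1200, cell_size=100.0)
        sd = mean.like(np.full((12, 12), 6.0))
        vg = VariogramModel("exponential", nugget=0.5, sill=3.0, range_m=400.0)
        _, se, _ = regional_inference(mean, sd, np.ones((12, 12), dtype=bool), vg)
        assert 6.0 / 12.0 <= se <= 6.0

    def test_empty_region_rejected(self):
        mean, sd = self.make_maps()
        with pytest.raises(UncertaintyError):
            regional_inference(mean, sd, np.zeros((10, 10), dtype=bool))


def _cv_training(seed, n=220, resid_sd=40.0, correlated=False):
    rng = np.random.default_rng(seed)
    L = 50_000.0
    x, y = rng.uniform(0, L, n), rng.uniform(0, L, n)
    h = rng.uniform(5, 45, n)
    agb = 10.43 * (0.66 * h) ** 1.19
    if correlated:
        grid = exponential_field((80, 80), L / 80, 0.7 * L, resid_sd**2, rng)
        cell = L / 80
        r = grid[np.clip((y / cell).astype(int), 0, 79),
                 np.clip((x / cell).astype(int), 0, 79)]
    else:
        r = rng.normal(0, resid_sd, n)
    train = pd.DataFrame({"x": x, "y": y, "agb": np.maximum(agb + r, 0.0),
                          "c1": h + rng.normal(0, 2, n)})
    bg = rng.uniform(0, 50, (1000, 1))
    return train, bg


class TestCrossValidation:
    def test_plotwise_deterministic_under_seed(self):
        train, bg = _cv_training(0)
        r1 = cv_plotwise(train, ["c1"], bg, k_folds=4, n_bins=6, seed=5)
        r2 = cv_plotwise(train, ["c1"], bg, k_folds=4, n_bins=6, seed=5)
        assert r1 == r2

    def test_fold_count_validation(self):
        train, bg = _cv_training(1)
        with pytest.raises(UncertaintyError):
            cv_plotwise(train, ["c1"], bg, k_folds=1)
        with pytest.raises(UncertaintyError):
            cv_latitudinal(train, ["c1"], bg, n_bands=1)

    def test_latitudinal_bands_are_contiguous(self):
        train, bg = _cv_training(2, n=120)
        res = cv_latitudinal(train, ["c1"], bg, n_bands=4, n_bins=5, seed=0)
        assert res["rmse"] > 0

    def test_uncorrelated_residuals_close_cv_schemes(self):
        """Without spatial structure in the residuals the two CV schemes
        estimate the same error (within 10% on average)."""
        ratios = []
        for s in range(6):
            train, bg = _cv_training(10 + s, correlated=False)
            p = cv_plotwise(train, ["c1"], bg, k_folds=5, n_bins=6, seed=s)
            l = cv_latitudinal(train, ["c1"], bg, n_bands=5, n_bins=6, seed=s)
            ratios.append(l["rmse"] / p["rmse"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_correlated_residuals_inflate_blocked_cv(self):
        """Long-range residual autocorrelation makes latitudinal CV error
        exceed plot-wise CV error in most replicates."""
        wins = 0
        for s in range(8):
            train, bg = _cv_training(30 + s, n=300, resid_sd=60.0,
                                     correlated=True)
            p = cv_plotwise(train, ["c1"], bg, k_folds=5, n_bins=6, seed=s)
            l = cv_latitudinal(train, ["c1"], bg, n_bands=5, n_bins=6, seed=s)
            wins += l["rmse"] > p["rmse"]
        assert wins >= 6
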