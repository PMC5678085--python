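import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from forestcarbon.maxent import (
    AGBMap,
    FeatureSpec,
    MaxEntError,
    bin_training_samples,
    fit_maxent_bin,
    fit_maxent_models,
    map_evaluation,
    predict_at_points,
    predict_map,
)
from forestcarbon.raster import RasterGrid


def frame(agb, **cov):
    df = pd.DataFrame({"agb": np.asarray(agb, dtype=float)})
    df["x"] = np.arange(len(df), dtype=float)
    df["y"] = 0.0
    for k, v in cov.items():
        df[k] = v
    return df


class TestBinning:
    def test_quantile_bins_nearly_equal_counts(self):
        rng = np.random.default_rng(0)
        samples = frame(rng.uniform(0, 500, 100))
        binning, labeled = bin_training_samples(samples, n_bins=10)
        counts = labeled["bin_id"].value_counts()
        assert counts.min() >= 9 and counts.max() <= 11

    def test_equal_width_edges(self):
        samples = frame(np.linspace(0, 500, 60))
        binning, _ = bin_training_samples(samples, n_bins=5, strategy="equal_width")
        np.testing.assert_allclose(binning.edges, [0, 100, 200, 300, 400, 500])

    def test_degenerate_samples_rejected(self):
        samples = frame(np.full(50, 200.0))
        with pytest.raises(MaxEntError):
            bin_training_samples(samples, n_bins=5)

    def test_centers_are_in_bin_medians(self):
        rng = np.random.default_rng(1)
        samples = frame(rng.uniform(0, 300, 90))
        binning, labeled = bin_training_samples(samples, n_bins=6)
        for k in range(binning.n_bins):
            sel = labeled["bin_id"] == k
            assert binning.centers[k] == np.median(labeled.loc[sel, "agb"])


class TestFit:
    def test_no_signal_weights_shrink_to_zero(self):
        bg = np.linspace(0, 5, 20)[:, None]
        spec = FeatureSpec(classes=("linear",)).fit_bounds(bg)
        m = fit_maxent_bin(bg, bg, spec=spec, beta=0.05)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-8)

    def test_high_value_presence_gets_positive_weight(self):
        bg = np.linspace(0, 5, 30)[:, None]
        pres = np.array([[4.0], [4.5], [5.0], [4.8], [4.2]])
        spec = FeatureSpec(classes=("linear",)).fit_bounds(bg)
        m = fit_maxent_bin(pres, bg, spec=spec, beta=0.05)
        assert m.weights[0] > 0

    def test_weights_match_grid_search_oracle(self):
        """Six background states, one linear feature: the optimizer agrees
        with brute-force maximisation of the penalised likelihood."""
        bg = np.arange(6, dtype=float)[:, None]
        pres = np.array([[3.0], [4.0], [5.0], [5.0], [4.0]])
        beta = 0.05
        spec = FeatureSpec(classes=("linear",)).fit_bounds(bg)
        m = fit_maxent_bin(pres, bg, spec=spec, beta=beta)
        fb, _ = spec.expand(bg)
        fp, _ = spec.expand(pres)
        lams = np.linspace(-30, 30, 600001)
        obj = (
            -fp.mean() * lams
            + logsumexp(fb[:, 0:1] * lams[None, :], axis=0)
            + beta * np.abs(lams)
        )
        oracle = lams[np.argmin(obj)]
        assert m.weights[0] == pytest.approx(oracle, abs=1e-3)

    def test_moment_matching_condition(self):
        rng = np.random.default_rng(2)
        bg = rng.uniform(0, 1, (200, 2))
        pres = rng.uniform(0.5, 1.0, (40, 2))
        beta = 0.1
        m = fit_maxent_bin(pres, bg, beta=beta)
        fb, _ = m.spec.expand(bg)
        fp, _ = m.spec.expand(pres)
        p = np.exp(fb @ m.weights - logsumexp(fb @ m.weights))
        gap = np.abs(fp.mean(axis=0) - fb.T @ p)
        assert (gap <= beta + 1e-4).all()

    def test_nonfinite_features_rejected(self):
        bg = np.ones((10, 1))
        bad = np.array([[np.inf]] * 6)
        with pytest.raises(MaxEntError):
            fit_maxent_bin(bad, bg)


class TestPredict:
    def make_models(self, seed=0, n=240, n_bins=6):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 50, n)
        agb = 10.43 * (0.66 * h) ** 1.19
        train = frame(agb, c1=h + rng.normal(0, 1.5, n))
        bg = rng.uniform(-2, 52, (1200, 1))
        binning, labeled = bin_training_samples(train, n_bins=n_bins)
        models = fit_maxent_models(labeled, binning, ["c1"], bg, beta=0.05)
        priors = np.bincount(labeled["bin_id"], minlength=n_bins) / n
        return models, binning, priors, train

    def test_posteriors_normalize(self):
        models, binning, priors, train = self.make_models()
        post, mean, sd = predict_at_points(
            models, binning, train[["c1"]].to_numpy(), priors
        )
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-6
        assert (sd >= 0).all()
        assert (mean >= binning.centers.min() - 1e-9).all()
        assert (mean <= binning.centers.max() + 1e-9).all()

    def test_equal_densities_return_priors(self):
        """When every bin model is the uniform background density, the
        posterior equals the prior (Bayes identity)."""
        bg = np.linspace(0, 1, 50)[:, None]
        spec = FeatureSpec(classes=("linear",)).fit_bounds(bg)
        from forestcarbon.maxent import MaxEntModel

        models = []
        for k in range(3):
            models.append(
                MaxEntModel(bin_id=k, weights=np.zeros(1), spec=spec,
                            beta=np.array([0.05]),
                            log_partition=float(np.log(len(bg))))
            )
        binning = type("B", (), {})()
        from forestcarbon.maxent import BiomassBinning

        binning = BiomassBinning(
            edges=np.array([0.0, 100.0, 200.0, 300.0]),
            centers=np.array([50.0, 150.0, 250.0]),
            strategy="quantile",
            within_bin_var=np.array([4.0, 4.0, 4.0]),
        )
        priors = np.array([0.5, 0.3, 0.2])
        x = np.array([[0.2], [0.8]])
        post, mean, sd = predict_at_points(models, binning, x, priors)
        np.testing.assert_allclose(post, np.tile(priors, (2, 1)), atol=1e-9)
        np.testing.assert_allclose(mean, priors @ binning.centers)

    def test_degenerate_posterior_returns_bin_stats(self):
        from forestcarbon.maxent import BiomassBinning, MaxEntModel

        bg = np.linspace(0, 1, 50)[:, None]
        spec = FeatureSpec(classes=("linear",)).fit_bounds(bg)
        strong = MaxEntModel(bin_id=0, weights=np.array([80.0]), spec=spec,
                             beta=np.array([0.05]), log_partition=0.0)
        weak = MaxEntModel(bin_id=1, weights=np.array([-80.0]), spec=spec,
                           beta=np.array([0.05]), log_partition=0.0)
        binning = BiomassBinning(
            edges=np.array([0.0, 100.0, 200.0]),
            centers=np.array([60.0, 160.0]),
            strategy="quantile",
            within_bin_var=np.array([9.0, 16.0]),
        )
        post, mean, sd = predict_at_points(
            [strong, weak], binning, np.array([[1.0]]), np.array([0.5, 0.5])
        )
        assert post[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert mean[0] == pytest.approx(60.0, rel=1e-6)
        assert sd[0] == pytest.approx(3.0, rel=1e-3)

    def test_monotone_covariate_yields_monotone_mean(self):
        models, binning, priors, _ = self.make_models(seed=3)
        sweep = np.linspace(0, 50, 60)[:, None]
        _, mean, _ = predict_at_points(models, binning, sweep, priors)
        diffs = np.diff(mean)
        assert (diffs >= -1e-6 * np.abs(mean[:-1])).all()

    def test_map_prediction_nodata_propagates(self):
        models, binning, priors, _ = self.make_models(seed=4)
        vals = np.full((5, 5), 25.0)
        vals[0, 0] = -9999.0
        cov = RasterGrid(vals, x0=0, y0=500, cell_size=100)
        agb_map = predict_map(models, binning, [cov], priors)
        assert agb_map.mean.values[0, 0] == agb_map.mean.nodata
        assert agb_map.sd.values[0, 0] == agb_map.sd.nodata
        assert agb_map.mean.values[1, 1] != agb_map.mean.nodata

    def test_rank_correlation_with_truth(self):
        """End-to-end: a single noisy monotone covariate recovers the biomass
        ranking (rank correlation > 0.8)."""
        from scipy.stats import spearmanr

        models, binning, priors, train = self.make_models(seed=5, n=400)
        _, mean, _ = predict_at_points(
            models, binning, train[["c1"]].to_numpy(), priors
        )
        rho = spearmanr(mean, train["agb"]).statistic
        assert rho > 0.8


class TestEvaluation:
    def make_map(self, values):
        grid = RasterGrid(np.asarray(values, dtype=float), x0=0, y0=200,
                          cell_size=100)
        sd = grid.like(np.zeros(grid.shape))
        return AGBMap(mean=grid, sd=sd)

    def test_perfect_map_zero_errors(self):
        amap = self.make_map([[100.0, 200.0], [300.0, 400.0]])
        ref = pd.DataFrame({"x": [50.0, 150.0], "y": [150.0, 150.0],
                            "agb": [100.0, 200.0]})
        rmse, msd, _ = map_evaluation(amap, ref)
        assert rmse == 0.0 and msd == 0.0

    def test_constant_offset(self):
        amap = self.make_map([[110.0, 210.0], [310.0, 410.0]])
        ref = pd.DataFrame({"x": [50.0, 150.0, 50.0, 150.0],
                            "y": [150.0, 150.0, 50.0, 50.0],
                            "agb": [100.0, 200.0, 300.0, 400.0]})
        rmse, msd, _ = map_evaluation(amap, ref)
        assert msd == pytest.approx(10.0)
        assert rmse == pytest.approx(10.0)

    def test_rmse_decomposition_identity(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 400, (6, 6))
        amap = self.make_map(vals)
        xs, ys = amap.mean.pixel_centers()
        gx, gy = np.meshgrid(xs, ys)
        ref = pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(),
                            "agb": vals.ravel() + rng.normal(0, 30, vals.size)})
        rmse, msd, scatter = map_evaluation(amap, ref)
        resid = scatter["predicted"] - scatter["observed"]
        assert rmse**2 == pytest.approx(msd**2 + resid.var(ddof=0), rel=1e-9)

    def test_disjoint_reference_rejected(self):
        amap = self.make_map([[1.0]])
        ref = pd.DataFrame({"x": [1e6], "y": [1e6], "agb": [5.0]})
        with pytest.raises(MaxEntError):
            map_evaluation(amap, ref)
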