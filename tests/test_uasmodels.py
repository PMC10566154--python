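import numpy as np
import pytest
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics.pairwise import rbf_kernel

from wheatfvc import groundfvc, synth, uasmodels
from wheatfvc.raster import fvc_raster
from wheatfvc.synth import EndmemberSpectra, PhotoColorModel
from wheatfvc.uasmodels import (
    DichotomyParams,
    compute_ndvi,
    dichotomy_fvc,
    hagfvc,
    predict_fvc_map,
    select_endmembers,
    train_rfr,
    train_svr,
)


def reflectance_samples(rng, n, spectra, noise=0.0, nir_saturation=None):
    truth = rng.random(n)
    side = int(np.ceil(np.sqrt(n)))
    pad = np.zeros(side * side)
    pad[:n] = truth
    f = fvc_raster(pad.reshape(side, side))
    sp = EndmemberSpectra(spectra.vegetation, spectra.soil, noise)
    r = synth.render_reflectance(
        f, sp, synth.UAS_BANDS, seed=int(rng.integers(2**31)), nir_saturation=nir_saturation
    )
    X = np.stack([r.band(b).ravel()[:n] for b in synth.UAS_BANDS], axis=1)
    return X, truth, r


class TestNdvi:
    def test_equal_bands_give_zero(self):
        r = fvc_raster(np.full((3, 3), 0.2)).with_data(
            np.stack([np.full((3, 3), 0.2)] * 2), bands=("red", "nir")
        )
        assert np.allclose(compute_ndvi(r).band("ndvi"), 0.0)

    def test_zero_red_gives_one(self):
        data = np.stack([np.zeros((2, 2)), np.full((2, 2), 0.5)])
        r = fvc_raster(np.zeros((2, 2))).with_data(data, bands=("red", "nir"))
        assert np.allclose(compute_ndvi(r).band("ndvi"), 1.0)

    def test_arithmetic(self):
        data = np.stack([np.full((1, 1), 0.1), np.full((1, 1), 0.5)])
        r = fvc_raster(np.zeros((1, 1))).with_data(data, bands=("red", "nir"))
        assert compute_ndvi(r).band("ndvi")[0, 0] == pytest.approx(2.0 / 3.0)

    def test_zero_denominator_is_nodata(self):
        data = np.stack([np.zeros((1, 1)), np.zeros((1, 1))])
        r = fvc_raster(np.zeros((1, 1))).with_data(data, bands=("red", "nir"))
        assert compute_ndvi(r).band("ndvi")[0, 0] == -9999.0


class TestDichotomy:
    def test_endmember_limits(self):
        params = DichotomyParams(0.1, 0.9)
        ndvi = fvc_raster(np.array([[0.9, 0.1, 0.5]])).with_data(
            np.array([[[0.9, 0.1, 0.5]]]), bands=("ndvi",)
        )
        out = dichotomy_fvc(ndvi, params).band("fvc")
        np.testing.assert_allclose(out, [[1.0, 0.0, 0.5]])

    def test_clipping_outside_endmembers(self):
        params = DichotomyParams(0.2, 0.8)
        ndvi = fvc_raster(np.zeros((1, 2))).with_data(
            np.array([[[0.05, 0.95]]]), bands=("ndvi",)
        )
        out = dichotomy_fvc(ndvi, params).band("fvc")
        np.testing.assert_allclose(out, [[0.0, 1.0]])

    def test_degenerate_endmembers_rejected(self):
        with pytest.raises(ValueError):
            DichotomyParams(0.5, 0.5)

    def test_exact_recovery_on_ndvi_linear_noiseless_scene(self, rng):
        spectra = EndmemberSpectra.ndvi_linear(noise_sd=0.0)
        f = fvc_raster(rng.random((30, 30)))
        r = synth.render_reflectance(f, spectra, synth.UAS_BANDS, seed=0)
        params = DichotomyParams(spectra.ndvi("soil"), spectra.ndvi("vegetation"))
        est = dichotomy_fvc(compute_ndvi(r), params)
        assert np.abs(est.band("fvc") - f.band("fvc")).max() < 1e-6


class TestEndmemberSelection:
    def test_percentiles_of_uniform_grid(self):
        vals = np.linspace(0, 1, 10001).reshape(1, -1)
        ndvi = fvc_raster(vals).with_data(vals[None], bands=("ndvi",))
        params = select_endmembers(ndvi, 5, 95)
        assert params.ndvi_s == pytest.approx(0.05, abs=2e-4)
        assert params.ndvi_v == pytest.approx(0.95, abs=2e-4)

    def test_constant_raster_rejected(self):
        vals = np.full((1, 100), 0.4)
        ndvi = fvc_raster(vals).with_data(vals[None], bands=("ndvi",))
        with pytest.raises(ValueError, match="degenerate"):
            select_endmembers(ndvi)

    def test_literal_override_passes_through(self):
        vals = np.full((1, 100), 0.4)
        ndvi = fvc_raster(vals).with_data(vals[None], bands=("ndvi",))
        params = select_endmembers(ndvi, ndvi_s=0.1, ndvi_v=0.9)
        assert (params.ndvi_s, params.ndvi_v) == (0.1, 0.9)


class TestRfr:
    def test_training_rmse_not_worse_than_holdout(self, rng):
        X, y, _ = reflectance_samples(rng, 400, EndmemberSpectra.default(), noise=0.02)
        cv = train_rfr(X[:300], y[:300], mtry_grid=(2,), ntree_grid=(100,), k_folds=5)
        err_tr = np.sqrt(np.mean((cv.model.predict(X[:300]) - y[:300]) ** 2))
        err_te = np.sqrt(np.mean((cv.model.predict(X[300:]) - y[300:]) ** 2))
        assert err_tr <= err_te

    def test_degenerate_forest_memorizes_noiseless_data(self, rng):
        X = rng.random((15, 4))
        y = np.clip(X @ [0.3, 0.2, 0.1, 0.4], 0, 1)
        cv = train_rfr(
            X, y, mtry_grid=(4,), ntree_grid=(1,), k_folds=3, bootstrap=False
        )
        np.testing.assert_allclose(cv.model.predict(X), y, atol=1e-12)

    def test_cv_rmse_small_on_linear_mixture_scene(self, rng):
        X, y, _ = reflectance_samples(rng, 500, EndmemberSpectra.default(), noise=0.01)
        cv = train_rfr(X, y, mtry_grid=(2, 4), ntree_grid=(100,), k_folds=5)
        assert cv.cv_rmse <= 0.06

    def test_grid_respects_feature_count_and_tie_breaks(self, rng):
        X, y, _ = reflectance_samples(rng, 80, EndmemberSpectra.default(), noise=0.01)
        cv = train_rfr(X, y, mtry_grid=(1, 2, 8), ntree_grid=(50,), k_folds=4)
        assert cv.best_params["mtry"] <= 4
        assert (cv.cv_table.cv_rmse >= cv.cv_rmse - 1e-12).all()

    def test_out_of_range_response_rejected(self, rng):
        with pytest.raises(ValueError):
            train_rfr(rng.random((30, 4)), rng.random(30) + 1.0)


class TestSvr:
    def test_prediction_matches_kernel_sum_oracle(self, rng):
        X, y, _ = reflectance_samples(rng, 80, EndmemberSpectra.default(), noise=0.02)
        cv = train_svr(X, y, gamma_grid=(0.5,), cost_grid=(2.0,), k_folds=4)
        scaler = cv.model.named_steps["standardscaler"]
        svr = cv.model.named_steps["svr"]
        Z = scaler.transform(X[:10])
        K = rbf_kernel(Z, svr.support_vectors_, gamma=svr.gamma)
        manual = K @ svr.dual_coef_.ravel() + svr.intercept_[0]
        np.testing.assert_allclose(manual, cv.model.predict(X[:10]), atol=1e-10)

    def test_training_point_predicted_within_tube(self, rng):
        X, y, _ = reflectance_samples(rng, 120, EndmemberSpectra.default(), noise=0.0)
        cv = train_svr(X, y, gamma_grid=(0.8,), cost_grid=(10.0,), k_folds=4)
        eps = cv.model.named_steps["svr"].epsilon
        resid = np.abs(cv.model.predict(X) - y)
        assert np.quantile(resid, 0.9) <= eps + 0.05

    def test_grid_search_minimizes_cv_rmse_with_cost_tie_break(self, rng):
        X, y, _ = reflectance_samples(rng, 60, EndmemberSpectra.default(), noise=0.02)
        cv = train_svr(X, y, gamma_grid=(0.2, 0.8), cost_grid=(1.0, 3.0), k_folds=4)
        table = cv.cv_table
        best_rmse = table.cv_rmse.min()
        winners = table[np.isclose(table.cv_rmse, best_rmse)]
        assert cv.best_params["cost"] == winners.cost.min()


class TestHagfvc:
    def test_agrees_with_mixture_threshold_on_separated_classes(self):
        # symmetric, well-separated classes: both estimators place the
        # threshold in the valley between the modes
        model = PhotoColorModel(veg_a_sd=5.0, bg_a_sd=5.0)
        photo, _, _ = synth.render_ground_photo(0.5, model, (256, 256), seed=21)
        res = hagfvc(photo)
        mix = groundfvc.fit_mixture(groundfvc.rgb_to_a_channel(photo))
        thr, _ = groundfvc.solve_threshold(mix)
        separation = model.bg_a_mean - model.veg_a_mean
        assert not res.degenerate
        assert abs(res.threshold - thr) <= 0.1 * separation
        assert abs(res.fvc - 0.5) < 0.02

    def test_single_class_tile_flagged_degenerate(self):
        photo, _, _ = synth.render_ground_photo(
            1.0, PhotoColorModel(), (64, 64), seed=22
        )
        assert hagfvc(photo).degenerate

    def test_fvc_bounded(self):
        for seed, target in [(30, 0.2), (31, 0.8)]:
            photo, _, _ = synth.render_ground_photo(
                target, PhotoColorModel(), (96, 96), seed=seed
            )
            res = hagfvc(photo)
            assert 0.0 <= res.fvc <= 1.0


class TestPredictMap:
    def test_constant_raster_gives_constant_prediction(self, rng):
        X, y, _ = reflectance_samples(rng, 200, EndmemberSpectra.default(), noise=0.01)
        cv = train_rfr(X, y, mtry_grid=(2,), ntree_grid=(100,), k_folds=5)
        const = fvc_raster(np.zeros((4, 4))).with_data(
            np.stack([np.full((4, 4), v) for v in (0.1, 0.1, 0.25, 0.4)]),
            bands=synth.UAS_BANDS,
        )
        out = predict_fvc_map(cv.model, const, synth.UAS_BANDS)
        assert np.ptp(out.band("fvc")) == 0.0

    def test_predictions_track_truth_on_synthetic_scene(self, rng):
        X, y, r = reflectance_samples(rng, 900, EndmemberSpectra.default(), noise=0.01)
        cv = train_rfr(X[:600], y[:600], mtry_grid=(2,), ntree_grid=(200,), k_folds=5)
        pred = cv.model.predict(X[600:])
        assert np.sqrt(np.mean((pred - y[600:]) ** 2)) <= 0.06

    def test_band_mismatch_rejected(self, rng):
        X, y, _ = reflectance_samples(rng, 60, EndmemberSpectra.default())
        cv = train_rfr(X, y, mtry_grid=(2,), ntree_grid=(50,), k_folds=3)
        sat = fvc_raster(np.zeros((2, 2))).with_data(
            np.zeros((3, 2, 2)), bands=synth.SAT_BANDS
        )
        with pytest.raises((KeyError, ValueError)):
            predict_fvc_map(cv.model, sat, synth.UAS_BANDS)


class TestSaturation:
    def test_dichotomy_degrades_faster_than_rfr_at_high_cover(self):
        rng = np.random.default_rng(77)
        spectra = EndmemberSpectra.default(noise_sd=0.005)
        X, y, r = reflectance_samples(
            rng, 3600, spectra, noise=0.005, nir_saturation=(0.7, 0.1)
        )
        tr, te = np.arange(1800), np.arange(1800, 3600)
        cv = train_rfr(X[tr], y[tr], mtry_grid=(2,), ntree_grid=(200,), k_folds=5)
        pred_rfr = np.clip(cv.model.predict(X[te]), 0, 1)
        ndvi = (X[te, 3] - X[te, 1]) / (X[te, 3] + X[te, 1])
        params = DichotomyParams(spectra.ndvi("soil"), spectra.ndvi("vegetation"))
        pred_dich = np.clip((ndvi - params.ndvi_s) / (params.ndvi_v - params.ndvi_s), 0, 1)
        hi = y[te] > 0.8
        err_dich = np.abs(pred_dich[hi] - y[te][hi]).mean()
        err_rfr = np.abs(pred_rfr[hi] - y[te][hi]).mean()
        assert err_dich > err_rfr
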