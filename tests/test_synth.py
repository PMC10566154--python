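import numpy as np
import pytest
from dataclasses import replace

from skimage import color

from wheatfvc import synth
from wheatfvc.raster import fvc_raster
from wheatfvc.synth import (
    ConfigurationError,
    EndmemberSpectra,
    PhotoColorModel,
    PlotRect,
    SceneConfig,
)


class TestFvcField:
    def test_degenerate_range_gives_constant_plots_and_bare_paths(self, small_scene):
        scene = replace_scene(small_scene, fvc_range=(0.5, 0.5), edge_taper_m=0.0)
        field = synth.generate_fvc_field(scene)
        mask = scene.plot_mask(field.grid)
        assert np.all(field.data[0][mask] == 0.5)
        assert np.all(field.data[0][~mask] == 0.0)

    def test_edge_taper_ramps_cover_near_plot_perimeter(self, small_scene):
        scene = replace_scene(small_scene, fvc_range=(0.5, 0.5), edge_taper_m=8.0)
        field = synth.generate_fvc_field(scene)
        g = field.grid
        # a pixel just inside a plot edge carries a fraction of the interior level
        plot = scene.plots[0]
        row, col = g.cell_of(plot.x0 + 1.0, plot.y0 + plot.height / 2)
        assert 0.0 < field.data[0][row, col] < 0.5
        # deep interior is untouched
        row, col = g.cell_of(plot.x0 + plot.width / 2, plot.y0 + plot.height / 2)
        assert field.data[0][row, col] == pytest.approx(0.5)

    def test_same_seed_reproduces_field_exactly(self, small_scene):
        a = synth.generate_fvc_field(small_scene)
        b = synth.generate_fvc_field(small_scene)
        np.testing.assert_array_equal(a.data, b.data)

    def test_range_respected_and_variogram_saturates_near_correlation_length(self):
        scene = SceneConfig.grid_layout(
            n_plot_rows=1,
            n_plot_cols=1,
            plot_w=120.0,
            plot_h=120.0,
            path_w=4.0,
            margin=0.0,
            stage="jointing",
            fvc_range=(0.2, 0.8),
            correlation_length_m=10.0,
            edge_taper_m=0.0,
            uas_gsd=0.5,
            seed=3,
        )
        field = synth.generate_fvc_field(scene)
        vals = field.data[0]
        assert vals.min() >= 0.0 and vals.max() <= 0.8
        assert 0.2 <= vals[vals > 0].mean() <= 0.8
        # empirical semivariogram along rows, gamma(h) = 0.5 E[(z(x+h)-z(x))^2]
        ell_px = int(scene.correlation_length_m / scene.uas_gsd)

        def gamma(h):
            d = vals[:, h:] - vals[:, :-h]
            return 0.5 * np.mean(d**2)

        g_short = gamma(max(ell_px // 4, 1))
        g_mid = gamma(ell_px)
        g_far = gamma(3 * ell_px)
        g_farther = gamma(5 * ell_px)
        assert g_short < g_mid < g_far  # rising limb
        assert abs(g_farther - g_far) < 0.5 * g_far  # flattening past the range

    def test_zero_area_plot_rejected(self):
        with pytest.raises(ConfigurationError):
            PlotRect(0, 0, 0, 10)

    def test_overlapping_plots_rejected(self):
        with pytest.raises(ConfigurationError):
            SceneConfig(
                width_m=50,
                height_m=50,
                plots=[PlotRect(0, 0, 30, 30), PlotRect(20, 20, 45, 45)],
            )


def replace_scene(scene, **kw):
    from dataclasses import replace

    return replace(scene, **kw)


class TestReflectance:
    def test_pure_vegetation_reproduces_endmember_spectrum(self):
        spectra = EndmemberSpectra.default(noise_sd=0.0)
        f = fvc_raster(np.ones((5, 5)))
        r = synth.render_reflectance(f, spectra, synth.UAS_BANDS, seed=0)
        for b in synth.UAS_BANDS:
            assert np.allclose(r.band(b), spectra.vegetation[b])

    def test_half_cover_mixes_linearly(self):
        spectra = EndmemberSpectra(
            vegetation={"green": 0.1, "red": 0.1, "rededge": 0.3, "nir": 0.5},
            soil={"green": 0.3, "red": 0.3, "rededge": 0.3, "nir": 0.3},
            noise_sd=0.0,
        )
        f = fvc_raster(np.full((4, 4), 0.5))
        r = synth.render_reflectance(f, spectra, ("red", "nir"), seed=0)
        assert np.allclose(r.band("red"), 0.2)
        assert np.allclose(r.band("nir"), 0.4)

    def test_noise_differs_by_seed_but_means_agree(self, rng):
        spectra = EndmemberSpectra.default(noise_sd=0.02)
        f = fvc_raster(rng.random((50, 50)))
        r1 = synth.render_reflectance(f, spectra, synth.UAS_BANDS, seed=1)
        r2 = synth.render_reflectance(f, spectra, synth.UAS_BANDS, seed=2)
        assert not np.array_equal(r1.data, r2.data)
        se = 0.02 / np.sqrt(f.data.size)
        for b in synth.UAS_BANDS:
            assert abs(r1.band(b).mean() - r2.band(b).mean()) < 3 * np.sqrt(2) * se

    def test_unknown_band_raises(self):
        f = fvc_raster(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            synth.render_reflectance(f, EndmemberSpectra.default(), ("swir",), seed=0)

    def test_endmember_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            EndmemberSpectra(
                vegetation={"red": 0.5, "nir": 0.4},  # NIR below red
                soil={"red": 0.2, "nir": 0.25},
            )


class TestSatelliteDegradation:
    def test_constant_raster_block_mean_is_constant(self):
        r = fvc_raster(np.full((10, 10), 0.37))
        coarse = synth.render_satellite_from_fine(r, 5)
        assert np.allclose(coarse.data, 0.37)
        assert coarse.gsd == 5.0

    def test_block_mean_arithmetic(self):
        r = fvc_raster(np.array([[0.1, 0.2], [0.3, 0.4]]))
        coarse = synth.render_satellite_from_fine(r, 2)
        assert coarse.data[0, 0, 0] == pytest.approx(0.25)

    def test_global_mean_is_conserved(self, rng):
        r = fvc_raster(rng.random((12, 18)))
        coarse = synth.render_satellite_from_fine(r, 6)
        assert coarse.data.mean() == pytest.approx(r.data.mean())

    def test_non_divisible_shape_rejected(self):
        with pytest.raises(ValueError):
            synth.render_satellite_from_fine(fvc_raster(np.zeros((7, 10))), 5)


class TestGroundPhoto:
    def test_zero_target_gives_all_background(self):
        _, mask, _ = synth.render_ground_photo(0.0, PhotoColorModel(), (32, 32), seed=0)
        assert not mask.any()

    def test_realized_fraction_within_one_pixel_quantum(self):
        _, mask, _ = synth.render_ground_photo(0.6, PhotoColorModel(), (64, 64), seed=1)
        assert abs(mask.mean() - 0.6) <= 1.0 / (64 * 64)

    def test_lab_round_trip_recovers_vegetation_a_mean(self):
        model = PhotoColorModel()
        photo, mask, clip_frac = synth.render_ground_photo(
            0.5, model, (128, 128), seed=2
        )
        assert clip_frac < 0.01
        a = color.rgb2lab(photo.astype(float) / 255.0)[..., 1]
        n = mask.sum()
        assert abs(a[mask].mean() - model.veg_a_mean) < 3 * model.veg_a_sd / np.sqrt(n) + 0.1

    def test_color_model_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            PhotoColorModel(veg_a_mean=5.0, bg_a_mean=-5.0)


class TestGroundSampling:
    def test_one_site_yields_five_subsquares(self, small_scene):
        table = synth.place_ground_samples(small_scene, 1, seed=0)
        assert len(table) == 5
        assert table.is_center.sum() == 1

    def test_site_truths_follow_five_point_definition(self, small_scene):
        field = synth.generate_fvc_field(small_scene)
        table = synth.place_ground_samples(small_scene, 3, seed=1)
        table = synth.sample_truth(field, table)
        for _, grp in table.groupby("site_id"):
            truth_10m = grp.truth_fvc.mean()
            truth_2m = grp[grp.is_center].truth_fvc.iloc[0]
            assert truth_10m == pytest.approx(grp.truth_fvc.mean())
            assert grp[grp.is_center].shape[0] == 1
            # the centre value alone defines the 2 m sample
            assert truth_2m in grp.truth_fvc.values

    def test_sites_fit_inside_plots(self, small_scene):
        table = synth.place_ground_samples(small_scene, 5, seed=2)
        centres = table[table.is_center]
        for _, rec in centres.iterrows():
            assert any(
                p.contains(rec.x, rec.y)
                and p.boundary_distance(rec.x, rec.y) >= 5.0 - 1e-9
                for p in small_scene.plots
            )

    def test_impossible_site_raises(self):
        scene = SceneConfig(
            width_m=30,
            height_m=30,
            plots=[PlotRect(0, 0, 8, 8)],  # too small for a 10 m site
            stage="jointing",
        )
        with pytest.raises(ConfigurationError):
            synth.place_ground_samples(scene, 1, seed=0)

    def test_bare_samples_sit_on_corridors(self, small_scene):
        table = synth.place_bare_samples(small_scene, 6, seed=3)
        assert len(table) == 6
        for _, rec in table.iterrows():
            assert not any(p.contains(rec.x, rec.y) for p in small_scene.plots)
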