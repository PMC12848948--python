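"""Generator contracts: determinism, ground-truth completeness, count
conservation, and the rendering guarantees the analysis stages rely on."""

import numpy as np
import pandas as pd
import pytest

from condensekit import brightfield as bf
from condensekit import synthetic as syn


class TestBrightfieldScenes:
    def test_same_spec_and_seed_is_bit_identical(self):
        spec = syn.BrightfieldSceneSpec(
            field_shape=(128, 128), n_fields=2, n_droplets_in_focus=5, seed=42
        )
        a, _ = syn.make_brightfield_set(spec)
        b, _ = syn.make_brightfield_set(spec)
        assert np.array_equal(a.frames, b.frames)

    def test_empty_spec_yields_no_droplets(self):
        spec = syn.BrightfieldSceneSpec(
            field_shape=(128, 128), n_fields=2, n_droplets_in_focus=0, n_droplets_defocus=0
        )
        images, truth = syn.make_brightfield_set(spec)
        assert len(truth.droplets) == 0
        assert images.n_fields == 2

    def test_ground_truth_lists_every_droplet(self):
        spec = syn.BrightfieldSceneSpec(
            field_shape=(512, 512), n_fields=1, n_droplets_in_focus=20, seed=3
        )
        _, truth = syn.make_brightfield_set(spec)
        assert len(truth.droplets) == 20
        assert truth.droplets["in_focus"].all()

    def test_rim_gradients_dominate_background(self):
        # on the noise-free template (smooth speckle only, no sharp dots),
        # rim-pixel gradients exceed 10x the background gradient SD
        spec = syn.BrightfieldSceneSpec(
            field_shape=(512, 512), n_fields=1, n_droplets_in_focus=20,
            n_speckle_dots=0, seed=3,
        )
        _, truth = syn.make_brightfield_set(spec)
        img = syn.noise_free_brightfield_field(spec, truth.droplets, 0)
        grad = bf.farid_gradient(img)
        yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        rim = np.zeros(img.shape, dtype=bool)
        near = np.zeros(img.shape, dtype=bool)
        for _, d in truth.droplets.iterrows():
            dist = np.hypot(yy - d["y"], xx - d["x"])
            rim |= np.abs(dist - d["radius_px"]) < 1.0
            near |= dist < d["radius_px"] + 4
        background = ~near
        assert grad[rim].mean() > 10.0 * grad[background].std()

    def test_defocused_droplets_are_blurred_copies(self):
        spec = syn.BrightfieldSceneSpec(
            field_shape=(256, 256), n_fields=1, n_droplets_in_focus=0,
            n_droplets_defocus=5, defocus_sigma_px=4.0, n_speckle_dots=0, seed=9,
        )
        _, truth = syn.make_brightfield_set(spec)
        img = syn.noise_free_brightfield_field(spec, truth.droplets, 0)
        grad = bf.farid_gradient(img)
        # same droplets rendered in focus give far sharper rims
        sharp = truth.droplets.assign(in_focus=True)
        spec_focus = syn.BrightfieldSceneSpec(
            field_shape=(256, 256), n_fields=1, n_droplets_in_focus=5,
            n_speckle_dots=0, seed=9,
        )
        img_f = syn.noise_free_brightfield_field(spec_focus, sharp, 0)
        assert bf.farid_gradient(img_f).max() > 4 * grad.max()

    @pytest.mark.parametrize(
        "bad",
        [
            {"field_shape": (0, 64)},
            {"n_droplets_in_focus": -1},
            {"droplet_radius_px": (0.0, 5.0)},
            {"n_fields": 0},
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            syn.BrightfieldSceneSpec(**bad)


class TestCondensateScenes:
    def test_no_enrichment_no_noise_is_constant(self):
        spec = syn.CondensateSceneSpec(enrichment=1.0, noise_model="none", seed=1)
        image, _ = syn.make_condensate_image(spec)
        assert np.all(image == spec.background_level)

    def test_noise_free_ratio_is_exact(self):
        spec = syn.CondensateSceneSpec(enrichment=5.0, noise_model="none", seed=2)
        image, truth = syn.make_condensate_image(spec)
        inner = image[truth.interior_mask > 0].mean()
        outer = image[truth.background_mask].mean()
        assert inner / outer == pytest.approx(5.0, abs=1e-12)

    def test_poisson_ratio_within_3se(self):
        # 50 condensates over 5 fields; ratio of means is unbiased for E
        ratios = []
        for seed in range(5):
            spec = syn.CondensateSceneSpec(
                enrichment=3.0, noise_model="poisson", background_level=100.0, seed=seed
            )
            image, truth = syn.make_condensate_image(spec)
            for i in range(1, truth.interior_mask.max() + 1):
                inner = image[truth.interior_mask == i].mean()
                ratios.append(inner / image[truth.background_mask].mean())
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert len(ratios) == 50
        assert abs(np.mean(ratios) - 3.0) < 3 * se

    def test_negative_enrichment_rejected(self):
        with pytest.raises(ValueError):
            syn.CondensateSceneSpec(enrichment=-0.5)


class TestFilamentScenes:
    def test_circle_count_follows_poisson(self):
        # expected count = density * 2*pi*R; tolerance 4*sqrt(expectation)
        spec = syn.FilamentSceneSpec(
            geometry="circle", unit_contour_length_nm=4000.0, seed=5
        )
        table, _, truth = syn.make_filament_localizations(spec)
        expected = spec.localization_density * truth.filaments[0]["arc_length_nm"]
        assert abs(len(table) - expected) < 4 * np.sqrt(expected)

    def test_single_unit_has_no_junction_puncta(self):
        spec = syn.FilamentSceneSpec(n_units_tethered=1, puncta_at_junctions=True, seed=6)
        _, puncta, truth = syn.make_filament_localizations(spec)
        assert len(puncta) == 0
        assert truth.filaments[0]["junction_arc_nm"] == []

    def test_tether_junctions_at_unit_boundaries(self):
        spec = syn.FilamentSceneSpec(
            geometry="line", n_units_tethered=3, puncta_at_junctions=True,
            field_extent_nm=30_000, seed=7,
        )
        _, puncta, truth = syn.make_filament_localizations(spec)
        fil = truth.filaments[0]
        L = fil["arc_length_nm"]
        assert fil["junction_arc_nm"] == pytest.approx([L / 3, 2 * L / 3], rel=1e-9)
        # puncta cluster around the true junction coordinates
        assert len(puncta) == 2 * spec.puncta_n_locs
        centers = truth.junction_puncta_nm
        for c in centers:
            d = np.hypot(puncta.x_nm - c[0], puncta.y_nm - c[1])
            assert d.min() < 3 * spec.puncta_sigma_nm

    def test_total_contour_length_is_k_times_unit(self):
        spec = syn.FilamentSceneSpec(geometry="curve", n_units_tethered=4, seed=8)
        _, _, truth = syn.make_filament_localizations(spec)
        assert truth.filaments[0]["arc_length_nm"] == pytest.approx(
            4 * spec.unit_contour_length_nm, rel=1e-6
        )

    def test_determinism_and_count_conservation(self):
        spec = syn.FilamentSceneSpec(geometry="curve", n_filaments=3, seed=11)
        t1, p1, _ = syn.make_filament_localizations(spec)
        t2, _, _ = syn.make_filament_localizations(spec)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            syn.FilamentSceneSpec(localization_density=0.0)


class TestBlinkMovies:
    def test_p_on_zero_gives_baseline_and_read_noise_only(self):
        emitters = syn.make_emitter_field(5, field_shape=(32, 32), min_sep_px=6, seed=1)
        spec = syn.BlinkMovieSpec(
            field_shape=(32, 32), n_frames=20, p_on=0.0, read_noise_sd=2.0, seed=1
        )
        movie, truth = syn.make_blink_movie(emitters, spec)
        assert len(truth.on_events) == 0
        assert abs(movie.mean() - spec.camera_baseline) < 0.1
        assert abs(movie.std() - spec.read_noise_sd) < 0.1

    def test_on_event_count_binomial(self):
        emitters = syn.make_emitter_field(20, field_shape=(64, 64), min_sep_px=5, seed=2)
        spec = syn.BlinkMovieSpec(field_shape=(64, 64), n_frames=200, p_on=0.05, seed=2)
        _, truth = syn.make_blink_movie(emitters, spec)
        n, p = 20 * 200, 0.05
        assert abs(len(truth.on_events) - n * p) < 4 * np.sqrt(n * p * (1 - p))

    def test_photon_conservation_fully_contained(self):
        emitters = np.array([[16.0, 16.0]])
        spec = syn.BlinkMovieSpec(
            field_shape=(32, 32), n_frames=1, p_on=1.0, camera_baseline=0.0,
            read_noise_sd=0.0, seed=3,
        )
        movie, truth = syn.make_blink_movie(emitters, spec)
        drawn = truth.on_events["photons"].iloc[0]
        assert movie[0].sum() == pytest.approx(drawn, abs=1e-9)

    def test_out_of_field_emitter_rejected(self):
        spec = syn.BlinkMovieSpec(field_shape=(32, 32))
        with pytest.raises(ValueError):
            syn.make_blink_movie(np.array([[40.0, 10.0]]), spec)

    def test_nonpositive_psf_rejected(self):
        with pytest.raises(ValueError):
            syn.BlinkMovieSpec(psf_sigma_px=0.0)


class TestAfmStacks:
    def test_single_frame_no_tilt_equals_base(self):
        base = np.arange(36, dtype=float).reshape(6, 6)
        stack, _ = syn.make_afm_stack(base, tilt=(0, 0), n_frames=1, noise_sd=0.0)
        assert np.array_equal(stack[0], base)

    def test_tilt_is_exact_plane(self):
        base = np.zeros((16, 16))
        stack, truth = syn.make_afm_stack(base, tilt=(0.5, -1.0), n_frames=3, noise_sd=0.0)
        yy, xx = np.mgrid[0:16, 0:16]
        assert np.allclose(stack - (0.5 * xx - 1.0 * yy), 0.0)
        assert truth.tilt == (0.5, -1.0)

    def test_median_rejects_single_outlier(self):
        base = np.random.default_rng(0).normal(size=(24, 24))
        stack, truth = syn.make_afm_stack(
            base, tilt=(0.1, 0.2), n_frames=5, outlier_frames=1, noise_sd=0.0, seed=4
        )
        (outlier,) = truth.outlier_frames
        clean = next(t for t in range(5) if t != outlier)
        assert np.array_equal(np.median(stack, axis=0), stack[clean])

    def test_too_many_outliers_rejected(self):
        with pytest.raises(ValueError):
            syn.make_afm_stack(np.zeros((8, 8)), n_frames=4, outlier_frames=2)
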