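"""DoFP mosaic forward model and snapshot reconstruction."""

import numpy as np
import pytest
from scipy import ndimage

from spe import dofp, scenes
from spe._seeding import substream
from spe.core import mueller_linear_retarder, apply_mueller

from conftest import IDEAL_CIRCULAR, reconstruct_maps


def uniform_scene(shape, stokes):
    return np.broadcast_to(np.asarray(stokes, float), shape + (4,)).copy()


class TestSimulateMosaic:
    def test_unpolarized_scene_gives_equal_orientations(self):
        frame = dofp.simulate_dofp_mosaic(
            uniform_scene((8, 8), [1, 0, 0, 0]), exposure_scale=100, quantize=False
        )
        assert np.allclose(frame.pixels, frame.pixels.flat[0])

    def test_malus_law_on_horizontal_linear_scene(self):
        frame = dofp.simulate_dofp_mosaic(
            uniform_scene((8, 8), [1, 1, 0, 0]), exposure_scale=100, quantize=False
        )
        masks = dofp._orientation_masks((8, 8))
        assert np.allclose(frame.pixels[masks[0.0]], 100.0)
        assert np.allclose(frame.pixels[masks[90.0]], 0.0, atol=1e-9)

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError):
            dofp.simulate_dofp_mosaic(uniform_scene((7, 8), [1, 0, 0, 0]))

    def test_quantization_clips_to_bitdepth(self):
        frame = dofp.simulate_dofp_mosaic(
            uniform_scene((4, 4), [10, 0, 0, 0]), exposure_scale=100, bitdepth=8
        )
        assert frame.pixels.max() == 255


class TestFixedPattern:
    def test_unit_calibration_is_identity(self, rng):
        pix = rng.integers(0, 255, (6, 6))
        frame = dofp.MosaicFrame(pix)
        out = dofp.correct_fixed_pattern(frame, dofp.CalibrationMap.identity((6, 6)))
        np.testing.assert_allclose(out, pix)

    def test_uniform_gain_halves_counts(self):
        frame = dofp.MosaicFrame(np.full((4, 4), 200))
        calib = dofp.CalibrationMap(np.full((4, 4), 2.0), np.zeros((4, 4)))
        np.testing.assert_allclose(dofp.correct_fixed_pattern(frame, calib), 100.0)

    def test_round_trip_removes_random_gain_field(self, rng):
        scene = uniform_scene((32, 32), [1, 0.2, -0.1, 0.3])
        gain = rng.uniform(0.8, 1.2, (32, 32))
        calib = dofp.CalibrationMap(gain, np.zeros((32, 32)))
        frame = dofp.simulate_dofp_mosaic(
            scene, calibration=calib, exposure_scale=100, quantize=False
        )
        corrected = dofp.correct_fixed_pattern(frame, calib)
        clean = dofp.simulate_dofp_mosaic(
            scene, exposure_scale=100, quantize=False
        ).pixels
        resid = corrected - clean
        assert np.var(resid) < 1e-10 * np.var(clean)

    def test_estimated_flat_field_calibration_matches_truth(self, rng):
        gain = rng.uniform(0.85, 1.15, (32, 32))
        calib = dofp.CalibrationMap(gain, np.zeros((32, 32)))
        flat = dofp.simulate_dofp_mosaic(
            uniform_scene((32, 32), [1, 0, 0, 0]),
            calibration=calib, exposure_scale=150, quantize=False,
        )
        est = dofp.estimate_calibration([flat])
        # gains are identifiable only up to each orientation's mean signal
        for _, mask in dofp._orientation_masks((32, 32)).items():
            np.testing.assert_allclose(
                est.gain[mask], gain[mask] / gain[mask].mean(), rtol=1e-9
            )

    def test_shape_mismatch_rejected(self):
        frame = dofp.MosaicFrame(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            dofp.correct_fixed_pattern(frame, dofp.CalibrationMap.identity((6, 6)))


class TestDemosaic:
    def test_constant_per_orientation_reproduced(self):
        vals = {90.0: 10.0, 45.0: 20.0, 135.0: 30.0, 0.0: 40.0}
        mosaic = np.zeros((8, 8))
        for angle, mask in dofp._orientation_masks((8, 8)).items():
            mosaic[mask] = vals[angle]
        sub = dofp.demosaic_bilinear(mosaic)
        assert np.allclose(sub.I90, 10) and np.allclose(sub.I45, 20)
        assert np.allclose(sub.I135, 30) and np.allclose(sub.I0, 40)

    def test_native_sites_kept_exactly(self, rng):
        mosaic = rng.uniform(0, 255, (16, 16))
        sub = dofp.demosaic_bilinear(mosaic)
        for angle, img in ((0.0, sub.I0), (45.0, sub.I45),
                           (90.0, sub.I90), (135.0, sub.I135)):
            mask = dofp._orientation_masks((16, 16))[angle]
            np.testing.assert_allclose(img[mask], mosaic[mask])

    def test_affine_ramp_interpolated_exactly_in_interior(self):
        ys, xs = np.indices((16, 16))
        mosaic = 3.0 + 0.5 * xs + 0.25 * ys  # same affine field per channel
        sub = dofp.demosaic_bilinear(mosaic)
        for img in (sub.I0, sub.I45, sub.I90, sub.I135):
            np.testing.assert_allclose(
                img[2:-2, 2:-2], mosaic[2:-2, 2:-2], atol=1e-10
            )

    def test_single_bright_pixel_spreads_bilinear_kernel(self):
        mosaic = np.zeros((12, 12))
        mosaic[6, 6] = 1.0  # a 0°-orientation native site (even-odd? check)
        # (6,6): row even, col even -> phase 0 -> 90° channel
        sub = dofp.demosaic_bilinear(mosaic)
        # unit impulse spreads with bilinear weights onto interleaved sites
        np.testing.assert_allclose(sub.I90[6, 6], 1.0)
        np.testing.assert_allclose(sub.I90[6, 7], 0.5)
        np.testing.assert_allclose(sub.I90[7, 7], 0.25)
        assert sub.I90.sum() == pytest.approx(4.0)  # kernel mass 4 per site


class TestPartialStokes:
    def test_linear_mode_arithmetic(self):
        ones = np.ones((2, 2))
        ps = dofp.partial_stokes_linear(
            dofp.SubImages(I0=ones, I45=ones, I90=ones, I135=ones)
        )
        assert np.allclose(ps.S0, 2) and np.allclose(ps.S1, 0)
        ps = dofp.partial_stokes_linear(
            dofp.SubImages(I0=ones, I45=0.5 * ones, I90=0 * ones, I135=0.5 * ones)
        )
        assert np.allclose(ps.S0, 1.0)  # (1 + 0.5 + 0 + 0.5) / 2
        assert np.allclose(ps.S1, 1) and np.allclose(ps.S2, 0)

    def test_circular_mode_arithmetic(self):
        half = 0.5 * np.ones((2, 2))
        ps = dofp.partial_stokes_circular(
            dofp.SubImages(I0=half, I45=half, I90=half, I135=half)
        )
        assert np.allclose(ps.S0, 1) and np.allclose(ps.S3, 0)

    def test_30deg_linear_scene_recovered(self):
        S = [1, np.cos(np.pi / 3), np.sin(np.pi / 3), 0]
        frame = dofp.simulate_dofp_mosaic(
            uniform_scene((16, 16), S), exposure_scale=1, quantize=False
        )
        ps = dofp.partial_stokes_linear(dofp.demosaic_bilinear(frame.pixels))
        np.testing.assert_allclose(ps.S0, 1, atol=1e-12)
        np.testing.assert_allclose(ps.S1, S[1], atol=1e-12)
        np.testing.assert_allclose(ps.S2, S[2], atol=1e-12)

    def test_right_circular_scene_fully_polarization_maintaining(self):
        frame = dofp.simulate_dofp_mosaic(
            uniform_scene((16, 16), [1, 0, 0, 1]),
            exposure_scale=1, quantize=False, mode="depolarization",
        )
        ps = dofp.partial_stokes_circular(dofp.demosaic_bilinear(frame.pixels))
        np.testing.assert_allclose(ps.S3 / ps.S0, 1.0, atol=1e-9)


class TestMaps:
    def test_retardance_map_values_and_invalid_pixels(self):
        S0 = np.array([[1.0, 1.0], [0.0, 1.0]])
        S1 = np.array([[0.0, 0.6], [0.3, 0.0]])
        ps = dofp.PartialStokesImage("retardance", S0=S0, S1=S1, S2=np.zeros((2, 2)))
        pm = dofp.retardance_map(ps)
        assert pm.values[0, 0] == 0 and pm.values[0, 1] == pytest.approx(0.6)
        assert not pm.valid[1, 0] and pm.valid[0, 1]

    def test_depolarization_map_values(self):
        ps = dofp.PartialStokesImage(
            "depolarization",
            S0=np.ones((1, 2)),
            S3=np.array([[1.0, 0.4]]),
        )
        pm = dofp.depolarization_map(ps)
        np.testing.assert_allclose(pm.values, [[0.0, 0.6]])

    def test_mode_mismatch_rejected(self):
        ps = dofp.PartialStokesImage("depolarization", S0=np.ones((2, 2)),
                                     S3=np.ones((2, 2)))
        with pytest.raises(ValueError):
            dofp.retardance_map(ps)

    def test_full_pipeline_quarter_wave_analytic_limit(self):
        """δ_L = π/3 pure-retarder scene under ideal circular probe:
        reconstructed A_δ = sin(π/3) to 1e-6."""
        delta = np.pi / 3
        M = mueller_linear_retarder(delta, 0.7)
        S = apply_mueller(M, IDEAL_CIRCULAR)
        maps = reconstruct_maps(uniform_scene((16, 16), S), quantize=False,
                                exposure_scale=1.0)
        pm, _ = maps["retardance"]
        np.testing.assert_allclose(pm.values, np.sin(delta), atol=1e-6)

    def test_retarder_overestimates_depolarization_as_one_minus_cos(self):
        """Pure retarder yields A_dep = 1 − |cos δ| despite zero true
        depolarization — the documented bias of the circular-ratio map."""
        for delta in (0, np.pi / 6, np.pi / 4, np.pi / 3, np.pi / 2):
            S = apply_mueller(mueller_linear_retarder(delta, 0.3), IDEAL_CIRCULAR)
            maps = reconstruct_maps(uniform_scene((8, 8), S), quantize=False,
                                    exposure_scale=1.0)
            pm, _ = maps["depolarization"]
            np.testing.assert_allclose(pm.values, 1 - abs(np.cos(delta)), atol=1e-9)


class TestExposureAndGamma:
    @pytest.mark.parametrize(
        "s0,valid", [(500.0, False), (10.0, False), (200.0, True)]
    )
    def test_threshold_cases_8bit(self, s0, valid):
        mask = dofp.exposure_mask(np.array([[s0]]), bitdepth=8)
        assert mask[0, 0] == valid

    def test_gamma_endpoints_and_quarter(self):
        assert dofp.gamma_correct(np.array(1.0)) == 1.0
        assert dofp.gamma_correct(np.array(0.0)) == 0.0
        assert dofp.gamma_correct(np.array(0.25), 0.5) == pytest.approx(0.5)

    def test_gamma_preserves_ordering(self, rng):
        x = rng.uniform(0, 1, 100)
        y = dofp.gamma_correct(x, 0.5)
        assert (np.argsort(x) == np.argsort(y)).all()

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            dofp.gamma_correct(np.array(0.5), 0.0)


class TestRender:
    def test_all_invalid_is_uniform_green(self):
        pm = dofp.ParameterMap(np.zeros((4, 4)), np.zeros((4, 4), bool), "A_delta")
        rgb = dofp.render_map(pm)
        assert (rgb == np.array([0, 255, 0], dtype=np.uint8)).all()

    def test_endpoints_hit_colormap_ends_and_no_mutation(self):
        vals = np.array([[0.0, 1.0]])
        pm = dofp.ParameterMap(vals.copy(), np.ones((1, 2), bool), "A_delta")
        import matplotlib

        lut = matplotlib.colormaps["viridis"]
        rgb = dofp.render_map(pm)
        np.testing.assert_array_equal(
            rgb[0, 0], (np.array(lut(0.0)[:3]) * 255).astype(np.uint8)
        )
        np.testing.assert_array_equal(
            rgb[0, 1], (np.array(lut(1.0)[:3]) * 255).astype(np.uint8)
        )
        dofp.render_map(pm)
        np.testing.assert_array_equal(pm.values, vals)


class TestPipelineProperties:
    def test_round_trip_piecewise_constant_scene(self, m_phantom_ideal):
        """simulate→demosaic→partial Stokes→maps recovers ground truth to
        1e-6 away from region boundaries (noise-free, unit gains)."""
        spec, truth = m_phantom_ideal
        S = scenes.scene_to_stokes(spec, truth)
        maps = reconstruct_maps(S, quantize=False, exposure_scale=1.0)
        interior = {
            lab: ndimage.binary_erosion(truth.labels == code, iterations=3)
            for lab, code in (("M", 5), ("bg", 0))
        }
        ret = maps["retardance"][0].values
        dep = maps["depolarization"][0].values
        assert np.abs(ret[interior["M"]] - np.sin(truth.delta[interior["M"]])).max() < 1e-6
        assert np.abs(ret[interior["bg"]]).max() < 1e-6
        # background is a pure depolarizer: A_dep = 1 - c exactly
        assert np.abs(
            dep[interior["bg"]] - (1 - truth.dep_c[interior["bg"]])
        ).max() < 1e-6

    def test_maps_invariant_to_global_intensity_scale(self, m_phantom_ideal):
        spec, truth = m_phantom_ideal
        S = scenes.scene_to_stokes(spec, truth)
        a = reconstruct_maps(S, quantize=False, exposure_scale=1.0)
        b = reconstruct_maps(S, quantize=False, exposure_scale=37.5)
        for mode in a:
            np.testing.assert_allclose(
                a[mode][0].values, b[mode][0].values, atol=1e-12
            )

    def test_patch_means_unbiased_under_shot_noise(self):
        """Monte-Carlo: 32×32 patch means of both maps are within 3
        standard errors of the noise-free truth at ~10^3-count signal."""
        delta, c = np.pi / 3, 0.5
        M = (np.diag([1.0, c, c, c]) @ mueller_linear_retarder(delta, 0.4))
        S = apply_mueller(M, IDEAL_CIRCULAR)
        scene = uniform_scene((32, 32), S)
        truth_vals = {"retardance": c * np.sin(delta),
                      "depolarization": 1 - c * abs(np.cos(delta))}
        for mode, expected in truth_vals.items():
            vals = []
            for rep in range(12):
                gen = substream(100 + rep, mode)
                frame = dofp.simulate_dofp_mosaic(
                    scene, exposure_scale=2000.0, shot_noise=True, rng=gen,
                    bitdepth=16, mode=mode,
                )
                sub = dofp.demosaic_bilinear(frame.pixels)
                if mode == "retardance":
                    pm = dofp.retardance_map(dofp.partial_stokes_linear(sub))
                else:
                    pm = dofp.depolarization_map(dofp.partial_stokes_circular(sub))
                vals.append(pm.values.mean())
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expected) < 3 * se
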