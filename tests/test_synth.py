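"""Scene generation and the SIM forward model."""

import numpy as np
import pytest
from skimage.measure import label

from simrestore import synth


class TestGenerateScene:
    def test_deterministic_under_fixed_seed(self):
        a = synth.generate_scene("filament", 128, 128, seed=1)
        b = synth.generate_scene("filament", 128, 128, seed=1)
        assert np.array_equal(a.density_map, b.density_map)

    def test_different_seeds_differ(self):
        a = synth.generate_scene("blob", 128, 128, seed=1)
        b = synth.generate_scene("blob", 128, 128, seed=2)
        assert not np.array_equal(a.density_map, b.density_map)

    def test_zero_spots_gives_empty_map(self):
        s = synth.generate_scene("puncta", 64, 64, {"n_spots": 0}, seed=0)
        assert s.is_empty
        assert np.all(s.density_map == 0)

    def test_filament_component_count_bounded(self):
        # each random-walk curve is one connected stroke, so the thresholded
        # map cannot split into more labelled components than curves other
        # than by leaving the canvas; checked with a labelling oracle
        s = synth.generate_scene(
            "filament", 128, 128,
            {"n_curves": 3, "length_frac": 0.3, "curvature": 0.02}, seed=5,
        )
        mask = s.density_map > 0.1 * s.density_map.max()
        n = label(mask, connectivity=2).max()
        assert 1 <= n <= 3

    def test_nonnegative_everywhere(self):
        for kind in synth.STRUCTURE_KINDS:
            s = synth.generate_scene(kind, 64, 64, seed=3)
            assert np.all(s.density_map >= 0)
            assert not s.is_empty

    def test_unknown_kind_rejected(self):
        with pytest.raises(synth.ConfigurationError, match="structure_kind"):
            synth.generate_scene("vesicle", 64, 64)

    def test_too_small_grid_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.generate_scene("puncta", 32, 32)


class TestOpticalModel:
    def test_cutoff_hand_value(self):
        # 2 NA / lambda in px units: 2*1.45/525nm * 60nm = 0.33143 cycles/px
        m = synth.make_optical_model(1.45, 525.0, 60.0, shape=(64, 64))
        assert m.cutoff == pytest.approx(2 * 1.45 / 525.0 * 60.0, abs=1e-12)
        assert m.cutoff == pytest.approx(0.331, abs=5e-4)

    def test_otf_normalized_and_bounded(self, optics128):
        assert optics128.otf[0, 0] == pytest.approx(1.0)
        fy = np.fft.fftfreq(128)[:, None]
        fx = np.fft.fftfreq(128)[None, :]
        beyond = np.hypot(fy, fx) >= optics128.cutoff
        assert np.all(optics128.otf[beyond] == 0)
        assert np.all(optics128.otf >= 0) and np.all(optics128.otf <= 1)

    def test_three_angles_five_phases_emit_15_pairs(self, optics128):
        pairs = optics128.frame_parameters()
        assert len(pairs) == 15
        # angle-major: first five share the first angle; phases distinct
        assert len({th for th, _ in pairs[:5]}) == 1
        assert len({round(ps, 9) for _, ps in pairs[:5]}) == 5

    def test_pattern_below_cutoff(self, optics128):
        mags = np.hypot(optics128.pattern_frequency[:, 0],
                        optics128.pattern_frequency[:, 1])
        assert np.all(mags < optics128.cutoff)

    def test_pattern_at_cutoff_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.make_optical_model(shape=(64, 64), pattern_frequency_fraction=1.0)

    def test_snap_places_pattern_on_grid(self):
        m = synth.make_optical_model(shape=(128, 128), snap_pattern_to_grid=True)
        assert np.allclose(m.pattern_frequency * 128, np.round(m.pattern_frequency * 128))


class TestSimulateRawStack:
    def test_empty_scene_all_zero(self, optics128, noise_free_acq):
        empty = synth.Scene(np.zeros((128, 128)), "puncta", 60.0, 0)
        st = synth.simulate_raw_stack(empty, optics128, noise_free_acq)
        assert np.all(st.frames == 0)

    def test_unmodulated_frames_identical(self, filament_scene, noise_free_acq):
        opt = synth.make_optical_model(shape=(128, 128), modulation_depth=0.0)
        st = synth.simulate_raw_stack(filament_scene, opt, noise_free_acq)
        assert np.allclose(st.frames, st.frames[0])

    def test_grid_mismatch_raises(self, optics128, noise_free_acq):
        small = synth.Scene(np.ones((64, 64)), "blob", 60.0, 0)
        with pytest.raises(synth.ConfigurationError, match="grid"):
            synth.simulate_raw_stack(small, optics128, noise_free_acq)

    def test_seed_determinism_with_noise(self, filament_scene, optics128):
        acq = synth.AcquisitionSettings(seed=7)
        a = synth.simulate_raw_stack(filament_scene, optics128, acq)
        b = synth.simulate_raw_stack(filament_scene, optics128, acq)
        assert np.array_equal(a.frames, b.frames)

    def test_point_modulation_recovers_m(self, optics128, noise_free_acq):
        # a single emitter's brightness across the 5 phases of one angle
        # follows A + B cos(psi + phi0) with B/A equal to the pattern depth
        pt = np.zeros((128, 128))
        pt[64, 64] = 1.0
        st = synth.simulate_raw_stack(
            synth.Scene(pt, "puncta", 60.0, 0), optics128, noise_free_acq
        )
        vals = st.frames[:5, 64, 64]
        psis = optics128.phases
        design = np.column_stack([np.ones(5), np.cos(psis), np.sin(psis)])
        a0, c, s = np.linalg.lstsq(design, vals, rcond=None)[0]
        assert np.hypot(c, s) / a0 == pytest.approx(
            optics128.modulation_depth, abs=1e-3
        )

    def test_phase_sum_equals_widefield(self, clean_stack, filament_scene, optics128):
        # evenly spaced phases: sum of cos terms vanishes, so the per-angle
        # phase sum reproduces n_phases x the unpatterned image
        wf = synth.blur_with_otf(filament_scene.density_map, optics128.otf)
        wf = np.clip(wf, 0, None)
        wf *= 200.0 / wf.max()
        for a in range(3):
            s = clean_stack.frames[5 * a: 5 * (a + 1)].sum(axis=0)
            assert np.allclose(s, 5 * wf, rtol=1e-10, atol=1e-8)

    def test_fourier_peak_ratio_matches_otf_weighted_m(self, noise_free_acq):
        # uniform scene: the frame spectrum has pattern peaks whose ratio to
        # DC is (m/2) * otf(k_p) exactly (grid-periodic pattern)
        opt = synth.make_optical_model(shape=(128, 128))
        st = synth.simulate_raw_stack(
            synth.Scene(np.ones((128, 128)), "blob", 60.0, 0), opt, noise_free_acq
        )
        spec = np.fft.fft2(st.frames[0])
        ky, kx = opt.pattern_frequency[0]
        iy, ix = int(round(ky * 128)) % 128, int(round(kx * 128)) % 128
        ratio = np.abs(spec[iy, ix]) / np.abs(spec[0, 0])
        otf_kp = synth.incoherent_otf(np.hypot(ky, kx), opt.cutoff)
        assert ratio == pytest.approx(opt.modulation_depth / 2 * otf_kp, abs=1e-6)


class TestLowLightPair:
    def test_identity_factor_identical(self, filament_scene, optics128):
        acq = synth.AcquisitionSettings(seed=3)
        a, b = synth.make_low_light_pair(filament_scene, optics128, acq, 1.0)
        assert np.array_equal(a.frames, b.frames)

    def test_expected_ratio_exact(self, filament_scene, optics128, noise_free_acq):
        a, b = synth.make_low_light_pair(
            filament_scene, optics128, noise_free_acq, 100.0
        )
        assert a.frames.mean() / b.frames.mean() == pytest.approx(100.0, abs=1e-9)

    def test_shot_noise_ratio_within_sampling_error(self, optics128):
        scene = synth.generate_scene("blob", 128, 128, seed=9)
        acq = synth.AcquisitionSettings(photon_budget=500.0, read_noise_sd=0.0, seed=11)
        a, b = synth.make_low_light_pair(scene, optics128, acq, 100.0)
        total_low = b.frames.sum()
        # Poisson: SE of the total is sqrt(total); propagate to the ratio
        ratio = a.frames.sum() / total_low
        se = 100.0 * np.sqrt(1.0 / total_low + 1.0 / a.frames.sum())
        assert abs(ratio - 100.0) <= 3 * se

    def test_invalid_factor_rejected(self, filament_scene, optics128, noise_free_acq):
        with pytest.raises(synth.ConfigurationError):
            synth.make_low_light_pair(filament_scene, optics128, noise_free_acq, 0.5)


class TestStackIO:
    def test_tiff_round_trip(self, clean_stack, tmp_path):
        path = tmp_path / "stack.tif"
        synth.write_stack(clean_stack, path)
        back = synth.read_stack(path)
        assert np.allclose(back.frames, clean_stack.frames, atol=1e-6)
        assert back.optics.n_angles == 3 and back.optics.n_phases == 5
        assert np.allclose(back.optics.pattern_frequency,
                           clean_stack.optics.pattern_frequency)
        assert back.frame_params == [
            (pytest.approx(t), pytest.approx(p)) for t, p in clean_stack.frame_params
        ]

    def test_frame_count_invariant(self, optics128, noise_free_acq):
        with pytest.raises(synth.ConfigurationError, match="frames"):
            synth.RawSimStack(
                np.zeros((9, 128, 128)),
                [(0.0, 0.0)] * 9,
                optics128,
                noise_free_acq,
            )
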