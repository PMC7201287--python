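"""Hybrid-counting chain: alignment, dark, noise model, quantization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoedt.counting import (NoiseModel, align_to_common_centre, binarize,
                              binarize_stack, estimate_dark, fit_noise_model,
                              hybridize, hybridize_stack)
from nanoedt.frame_io import FrameStack4D, ScanGeometry

GEOM = ScanGeometry(step_nm=40.0, probe_fwhm_nm=12.0)


def _stack_of(frames):
    frames = np.asarray(frames)
    return FrameStack4D(frames[None], GEOM, "raw_adu")


class TestAlignment:
    def _delta_stack(self, offsets, det=17, amp=1000):
        frames = np.zeros((1, len(offsets), det, det), dtype=np.int32)
        c = det // 2
        for i, (dr, dc) in enumerate(offsets):
            frames[0, i, c + dr, c + dc] = amp
        return FrameStack4D(frames, GEOM, "raw_adu")

    def test_delta_at_centre_needs_no_shift(self):
        stack = self._delta_stack([(0, 0)])
        _, res = align_to_common_centre(stack, 3)
        assert tuple(res.shifts[0, 0]) == (0, 0)

    def test_offset_delta_gets_opposite_shift(self):
        stack = self._delta_stack([(2, -3)])
        aligned, res = align_to_common_centre(stack, 3)
        assert tuple(res.shifts[0, 0]) == (-2, 3)
        c = 17 // 2
        assert aligned.data[0, 0, c, c] == 1000

    def test_known_per_frame_offsets_all_recovered(self):
        offsets = [(0, 0), (1, 2), (-2, 1), (3, -3), (-1, -1)]
        stack = self._delta_stack(offsets)
        _, res = align_to_common_centre(stack, 4)
        for i, (dr, dc) in enumerate(offsets):
            assert tuple(res.shifts[0, i]) == (-dr, -dc)

    def test_beamless_frame_is_flagged_not_shifted(self):
        frames = np.zeros((1, 1, 9, 9), dtype=np.int32)
        stack = FrameStack4D(frames, GEOM, "raw_adu")
        _, res = align_to_common_centre(stack, 2, sigma_adu=5.0)
        assert res.unalignable[0, 0]
        assert tuple(res.shifts[0, 0]) == (0, 0)

    def test_simulated_beam_jitter_recovered(self):
        from nanoedt.simulator import SimulationConfig, simulate_tilt_series
        cfg = SimulationConfig(scan_shape=(4, 6), det_shape=(48, 48),
                               tilt_min_deg=0, tilt_max_deg=0,
                               beam_jitter_px=3, support_thickness_nm=0.0,
                               seed=21)
        stacks, gt = simulate_tilt_series(cfg)
        _, res = align_to_common_centre(stacks[0], 8)
        np.testing.assert_array_equal(res.shifts, -gt.beam_offsets[0])


class TestDark:
    def test_constant_frames(self):
        frames = np.full((4, 5, 6, 6), 7, dtype=np.int32)
        dark = estimate_dark(FrameStack4D(frames, GEOM, "raw_adu"))
        np.testing.assert_array_equal(dark, 7)

    def test_median_ignores_one_bright_frame_in_99(self):
        frames = np.full((9, 11, 4, 4), 10, dtype=np.int32)
        frames[0, 0, 2, 2] = 5000
        dark = estimate_dark(FrameStack4D(frames, GEOM, "raw_adu"))
        assert dark[2, 2] == 10

    def test_too_few_frames_rejected(self):
        frames = np.zeros((3, 5, 4, 4), dtype=np.int32)
        with pytest.raises(ValueError, match="16"):
            estimate_dark(FrameStack4D(frames, GEOM, "raw_adu"))

    def test_zero_dose_simulation_recovers_dark_level(self):
        """On a signal-free stack the worst pixel of the dark map stays
        within 5 true standard errors of a temporal median (1.253 sigma/vN),
        plus half an ADU of integer quantization."""
        from nanoedt.simulator import SimulationConfig, simulate_tilt_series
        cfg = SimulationConfig(scan_shape=(12, 12), det_shape=(16, 16),
                               tilt_min_deg=0, tilt_max_deg=0,
                               dose_e_per_A2_per_frame=0.0,
                               bg_rate_e_per_px=0.0, seed=6)
        stacks, _ = simulate_tilt_series(cfg)
        dark = estimate_dark(stacks[0], outlier_sigma=None)
        se = 1.253 * cfg.read_noise_sigma_adu / np.sqrt(stacks[0].n_frames)
        assert np.abs(dark - cfg.dark_level_adu).max() <= 5 * se + 0.5

    def test_persistent_beam_does_not_leak_into_dark(self, sim_small):
        cfg, stacks, _ = sim_small
        dark = estimate_dark(stacks[0])
        assert np.abs(dark - cfg.dark_level_adu).max() < 3 * \
            cfg.read_noise_sigma_adu


class TestNoiseModel:
    def test_pure_gaussian_residuals_recover_sigma_and_threshold(self):
        rng = np.random.default_rng(3)
        frames = np.rint(rng.normal(0.0, 5.0, size=(8, 8, 24, 24)))
        stack = FrameStack4D(frames.astype(np.int32), GEOM, "raw_adu")
        model = fit_noise_model(stack, np.zeros((24, 24)), k_sigma=4,
                                gain_adu_per_electron=32.0)
        assert abs(model.sigma_adu - 5.0) < 0.5
        assert abs(model.threshold_adu - 20.0) < 2.0

    def test_all_identical_residuals_degenerate(self):
        frames = np.full((4, 5, 4, 4), 100, dtype=np.int32)
        stack = FrameStack4D(frames, GEOM, "raw_adu")
        with pytest.raises(ValueError, match="degenerate"):
            fit_noise_model(stack, np.full((4, 4), 100.0))

    def test_gain_estimated_within_ten_percent(self, sim_small):
        cfg, stacks, _ = sim_small
        dark = estimate_dark(stacks[2])
        model = fit_noise_model(stacks[2], dark, k_sigma=4)
        assert abs(model.gain_adu_per_electron - cfg.gain_adu_per_electron) \
            < 0.1 * cfg.gain_adu_per_electron

    def test_sidecar_roundtrip(self, tmp_path):
        m = NoiseModel(np.full((3, 3), 99.5), 5.0, 32.0, 20.0)
        m.save(tmp_path / "noise.txt")
        back = NoiseModel.load(tmp_path / "noise.txt")
        assert back.sigma_adu == 5.0
        assert back.gain_adu_per_electron == 32.0
        np.testing.assert_allclose(back.dark_map, m.dark_map)


class TestQuantization:
    def test_rule_examples(self, exact_model):
        model = NoiseModel(np.zeros((1, 1)), 5.0, 32.0, 20.0)
        frame = np.array([[35.0, 70.0, 19.0, 0.0]])
        np.testing.assert_array_equal(hybridize(frame, model), [[1, 2, 0, 0]])
        np.testing.assert_array_equal(binarize(frame, model), [[1, 1, 0, 0]])

    def test_all_subthreshold_is_zero(self, exact_model):
        frame = np.full((5, 5), 10.0)
        assert hybridize(frame, exact_model).sum() == 0
        assert binarize(frame, exact_model).sum() == 0

    def test_noiseless_hybrid_counts_equal_true_arrivals(self, sim_noiseless,
                                                         exact_model):
        _, stacks, gt = sim_noiseless
        hyb = hybridize_stack(stacks[0], exact_model)
        np.testing.assert_array_equal(hyb.data, gt.electron_counts[0])

    def test_binary_underestimates_with_coincidence(self, sim_noiseless,
                                                    exact_model):
        _, stacks, gt = sim_noiseless
        true = gt.electron_counts[0].sum()
        hyb = hybridize_stack(stacks[0], exact_model).data.sum()
        bin_ = binarize_stack(stacks[0], exact_model).data.sum()
        assert bin_ < hyb <= true

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_and_binary_below_hybrid(self, seed):
        rng = np.random.default_rng(seed)
        model = NoiseModel(np.zeros((1, 1)),
                           sigma_adu=float(rng.uniform(1, 10)),
                           gain_adu_per_electron=float(rng.uniform(5, 60)),
                           threshold_adu=float(rng.uniform(1, 40)))
        a = rng.normal(0, 100, size=(8, 8))
        bump = rng.uniform(0, 50, size=(8, 8))
        ha, hb = hybridize(a, model), hybridize(a + bump, model)
        assert (hb >= ha).all()                       # monotone per pixel
        assert (binarize(a, model) <= ha).all()       # binary <= hybrid
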