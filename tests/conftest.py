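"""Shared fixtures: small seeded synthetic acquisitions.

Simulation sizes are scaled well below the real experiment (30x70 scan,
90 tilts, ~1792 px detector) to keep the suite fast; dose, gain, noise and
scan geometry stay at the stated experimental values.
"""

import numpy as np
import pytest

from nanoedt import NoiseModel, SimulationConfig, simulate_tilt_series


@pytest.fixture(scope="session")
def sim_small():
    """Five-tilt acquisition on a 64 px detector: counting-scale world."""
    cfg = SimulationConfig.default(scan_shape=(10, 14), det_shape=(64, 64),
                                   tilt_min_deg=-2, tilt_max_deg=2, seed=7)
    stacks, gt = simulate_tilt_series(cfg)
    return cfg, stacks, gt


@pytest.fixture(scope="session")
def sim_noiseless():
    """Noise-free detector (zero read noise, zero dark): counting oracle."""
    cfg = SimulationConfig.default(scan_shape=(8, 10), det_shape=(64, 64),
                                   tilt_min_deg=0, tilt_max_deg=0,
                                   read_noise_sigma_adu=0.0,
                                   dark_level_adu=0.0, seed=11)
    stacks, gt = simulate_tilt_series(cfg)
    return cfg, stacks, gt


@pytest.fixture(scope="session")
def sim_seg():
    """Single-tilt scan on a 128 px detector: segmentation/thickness world."""
    cfg = SimulationConfig.default(scan_shape=(20, 28), det_shape=(128, 128),
                                   tilt_min_deg=0, tilt_max_deg=0, seed=3)
    stacks, gt = simulate_tilt_series(cfg)
    return cfg, stacks, gt


@pytest.fixture(scope="session")
def sim_two_crystals():
    """Two adjacent crystallites with rotated lattices in one field of view."""
    cfg = SimulationConfig.default(scan_shape=(24, 28), det_shape=(128, 128),
                                   tilt_min_deg=0, tilt_max_deg=0,
                                   two_crystals=True, seed=5)
    stacks, gt = simulate_tilt_series(cfg)
    return cfg, stacks, gt


@pytest.fixture(scope="session")
def sim_peaks():
    """Full-detector-resolution world where the bin-5 / 6-px-template
    peak-finder defaults are meaningful (spots ~6 binned px across, as on
    the real ~1792 px detector)."""
    cfg = SimulationConfig.default(scan_shape=(6, 8), det_shape=(512, 512),
                                   tilt_min_deg=0, tilt_max_deg=0,
                                   spot_sigma_px=6.0, beam_sigma_px=4.0,
                                   seed=13)
    stacks, gt = simulate_tilt_series(cfg)
    return cfg, stacks, gt


@pytest.fixture()
def exact_model():
    """Noise model with the generator's exact gain and a mid-gain threshold."""
    return NoiseModel(dark_map=np.zeros((1, 1)), sigma_adu=5.0,
                      gain_adu_per_electron=32.0, threshold_adu=16.0)
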