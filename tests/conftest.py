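"""Shared fixtures: small, fast simulated scenes.

Unit tests run on reduced scene sizes (~128-160 px, 16-24 frames) so the
suite stays quick; the acceptance tests use the full default conditions.
"""

import dataclasses

import numpy as np
import pytest

from qube import SimulationParams, simulate_sequence


def small_params(**overrides) -> SimulationParams:
    """Compact scene: everything scaled to 128 px, defaults otherwise."""
    kw = dict(
        dims=(128, 128), n_frames=16,
        blush_center=(72.0, 72.0), blush_sigma_px=24.0, blush_amplitude=30.0,
        roi_half_side_px=20.0,
        diaphragm_edge_row=108.0, diaphragm_soft_width_px=6.0,
        t0_s=0.3, tp_s=0.5, alpha=3.0,
        vessel_t0_s=0.1, vessel_tp_s=0.3,
        panning_drift_px=(0.1, 0.15),
        seed=7,
    )
    kw.update(overrides)
    return SimulationParams(**kw)


@pytest.fixture(scope="session")
def small_scene():
    """One small noisy moving scene with all structures, plus ground truth."""
    return simulate_sequence(small_params())


@pytest.fixture(scope="session")
def small_clean_scene():
    """Small structure-free, motionless, noise-free, unquantized scene."""
    p = small_params(noise_sigma=0.0, bit_depth=None,
                     include_vessels=False, include_diaphragm=False,
                     include_catheter=False,
                     translation_amplitude_px=(0.0, 0.0),
                     rotation_amplitude_deg=0.0, panning_drift_px=(0.0, 0.0))
    return simulate_sequence(p)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
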