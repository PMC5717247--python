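"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pytest

from patternlight.design import DesignConfig, make_design
from patternlight.simulate import SignalParams, make_pattern_atlas, simulate_tmaps
from patternlight.volume import VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return VolumeGrid.isotropic((8, 9, 7), voxel_mm=2.0)


@pytest.fixture(scope="session")
def tiny_atlas():
    """A small single-task atlas used by several suites."""
    return make_pattern_atlas(dims=(14, 14, 12), voxel_mm=2.0,
                              tasks=("listening",), region_size_vox=40,
                              margin_vox=2, share_tone_with=None, seed=3)


@pytest.fixture(scope="session")
def tiny_design():
    cfg = DesignConfig(n_subjects=2, tasks=("listening",), seed=3)
    return cfg, make_design(cfg)


@pytest.fixture(scope="session")
def tiny_tmaps(tiny_atlas, tiny_design):
    """Signal-bearing per-trial maps for 2 subjects on the tiny atlas."""
    _, trials = tiny_design
    params = SignalParams(effect_amplitude=1.5, seed=3)
    return simulate_tmaps(trials, tiny_atlas, params)
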