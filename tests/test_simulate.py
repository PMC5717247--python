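"""Synthetic data generator: atlas packing, noise, planted patterns."""

import numpy as np
import pytest
from scipy import ndimage

from patternlight.design import DesignConfig, make_design
from patternlight.simulate import (DEFAULT_HRF, PatternAtlas, SignalParams,
                                   make_pattern_atlas, simulate_bold,
                                   simulate_tmaps, smooth_noise)
from patternlight.volume import VolumeGrid


def test_atlas_geometry():
    atlas = make_pattern_atlas(dims=(24, 24, 20), region_size_vox=60,
                               margin_vox=3, seed=1)
    assert set(atlas.regions) == {"tone", "listening", "imagery", "production"}
    for t, reg in atlas.regions.items():
        assert reg.sum() == 60
        assert not np.any(reg & ~atlas.mask)
        # compact: one connected component
        _, n = ndimage.label(reg)
        assert n == 1
    # tone shares voxels with listening, all other pairs disjoint
    assert np.array_equal(atlas.regions["tone"], atlas.regions["listening"])
    for a in ("listening", "imagery", "production"):
        for b in ("imagery", "production"):
            if a != b:
                assert not np.any(atlas.regions[a] & atlas.regions[b])
    # margin: disjoint regions are separated by > margin voxels
    dil = ndimage.binary_dilation(atlas.regions["imagery"], iterations=3)
    assert not np.any(dil & atlas.regions["production"])


def test_atlas_validation():
    grid = VolumeGrid.isotropic((6, 6, 6))
    mask = np.ones((6, 6, 6), dtype=bool)
    reg = np.zeros_like(mask)
    reg[0, 0, 0] = True
    with pytest.raises(ValueError):
        PatternAtlas(grid=grid, mask=mask, regions={"a": reg, "b": reg})
    out = np.zeros_like(mask)
    out[0, 0, 0] = True
    with pytest.raises(ValueError):
        PatternAtlas(grid=grid, mask=~out, regions={"a": out})


def test_infeasible_packing_raises():
    with pytest.raises(ValueError, match="infeasible"):
        make_pattern_atlas(dims=(8, 8, 8), region_size_vox=200, seed=0)


def test_smooth_noise_properties(rng):
    fields = smooth_noise((20, 20, 16), fwhm_mm=4.0, voxel_mm=2.0, rng=rng, n=8)
    assert fields.shape == (8, 20, 20, 16)
    assert fields.std() == pytest.approx(1.0, rel=1e-6)
    # smoothing induces positive lag-1 autocorrelation
    r = np.corrcoef(fields[0, :-1].ravel(), fields[0, 1:].ravel())[0, 1]
    assert r > 0.3
    rough = smooth_noise((20, 20, 16), fwhm_mm=0.0, voxel_mm=2.0,
                         rng=np.random.default_rng(0), n=1)
    r0 = np.corrcoef(rough[0, :-1].ravel(), rough[0, 1:].ravel())[0, 1]
    assert abs(r0) < 0.1


def test_tmaps_signal_placement(tiny_atlas, tiny_design):
    cfg, trials = tiny_design
    params = SignalParams(effect_amplitude=3.0, seed=5)
    tmaps = simulate_tmaps(trials, tiny_atlas, params)
    assert set(tmaps) == {(s, "listening") for s in (1, 2)}
    tm = tmaps[(1, "listening")]
    assert tm.data.shape == (42, tiny_atlas.mask_indices.size)
    rvec = tiny_atlas.regions["listening"].ravel(order="F")[tiny_atlas.mask_indices]
    # class means separate inside the region, not outside
    y = tm.labels
    inside = np.var([tm.data[y == c][:, rvec].mean(axis=0) for c in range(1, 8)],
                    axis=0).mean()
    outside = np.var([tm.data[y == c][:, ~rvec].mean(axis=0) for c in range(1, 8)],
                     axis=0).mean()
    assert inside > 5 * outside


def test_pattern_consistency_extremes(tiny_atlas, tiny_design):
    cfg, trials = tiny_design
    rvec = tiny_atlas.regions["listening"].ravel(order="F")[tiny_atlas.mask_indices]

    def class_means(params):
        tmaps = simulate_tmaps(trials, tiny_atlas, params)
        out = {}
        for s in (1, 2):
            tm = tmaps[(s, "listening")]
            y = tm.labels
            out[s] = np.stack([tm.data[y == c][:, rvec].mean(axis=0)
                               for c in range(1, 8)])
        return out

    same = class_means(SignalParams(effect_amplitude=4.0,
                                    subject_pattern_consistency=1.0, seed=2))
    r_same = np.corrcoef(same[1].ravel(), same[2].ravel())[0, 1]
    diff = class_means(SignalParams(effect_amplitude=4.0,
                                    subject_pattern_consistency=0.0, seed=2))
    r_diff = np.corrcoef(diff[1].ravel(), diff[2].ravel())[0, 1]
    assert r_same > 0.8
    assert abs(r_diff) < 0.3


def test_amplitude_zero_is_pure_noise(tiny_atlas, tiny_design):
    _, trials = tiny_design
    tmaps = simulate_tmaps(trials, tiny_atlas,
                           SignalParams(effect_amplitude=0.0, seed=4))
    tm = tmaps[(1, "listening")]
    assert abs(tm.data.mean()) < 0.05
    # determinism: same seed, same data
    again = simulate_tmaps(trials, tiny_atlas,
                           SignalParams(effect_amplitude=0.0, seed=4))
    np.testing.assert_array_equal(tm.data, again[(1, "listening")].data)


def test_bold_rejects_overlap(tiny_atlas):
    cfg = DesignConfig(n_subjects=1, tasks=("listening",), stim_s=2.0,
                       rest_s=3.0)  # 5 s trials -> 2 TR spacing < len(hrf)
    trials = make_design(cfg)
    with pytest.raises(ValueError, match="[Oo]verlap"):
        simulate_bold(trials, tiny_atlas, SignalParams(seed=0))


def test_bold_boxcar_recovery(tiny_atlas, tiny_design):
    """With a 1-TR boxcar response and tiny noise, the BOLD series carries the
    planted pattern exactly at the event TR."""
    _, trials = tiny_design
    one = trials[trials["subject"] == 1]
    params = SignalParams(effect_amplitude=5.0, noise_sd=1e-6, seed=6)
    runs = simulate_bold(one, tiny_atlas, params, hrf=np.array([1.0]))
    run = runs[(1, "listening")]
    assert run.data.shape[1] == tiny_atlas.mask_indices.size
    on = run.onsets_tr
    # lead-in rest shifts every onset by 10 s = 4 TRs
    np.testing.assert_array_equal(
        on, (run.trials["event_onset_s"].to_numpy() / run.tr_s).astype(int) + 4)
    rvec = tiny_atlas.regions["listening"].ravel(order="F")[tiny_atlas.mask_indices]
    ev = run.data[on][:, rvec] - 100.0
    base = run.data[on + 1][:, rvec] - 100.0
    assert np.abs(ev).mean() > 1.0
    assert np.abs(base).mean() < 1e-3


def test_default_hrf_peaks_at_third_bin():
    assert int(np.argmax(DEFAULT_HRF)) == 3
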