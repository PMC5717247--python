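"""Group inference: permutation nulls, p-values, smoothness, clusters."""

import numpy as np
import pandas as pd
import pytest

from patternlight.design import DesignConfig, make_design
from patternlight.inference import (NullDistribution, cluster_threshold_mc,
                                    cluster_threshold_perm,
                                    connectivity_structure, estimate_fwhm,
                                    extract_clusters, group_average,
                                    permutation_null,
                                    permute_labels_within_units, voxelwise_p)
from patternlight.simulate import smooth_noise
from patternlight.volume import MaskedVector, VolumeGrid


def _mv(grid, idx, vals):
    return MaskedVector(grid, idx, np.asarray(vals, dtype=float))


def test_group_average(small_grid):
    idx = np.arange(4)
    a = _mv(small_grid, idx, [1, 2, 3, np.nan])
    b = _mv(small_grid, idx, [3, 2, 1, 5])
    g = group_average([a, b])
    np.testing.assert_allclose(g.values, [2, 2, 2, 5])
    with pytest.raises(ValueError):
        group_average([a])


def test_permute_labels_within_units(rng):
    trials = make_design(DesignConfig(n_subjects=1, tasks=("listening",)))
    y = permute_labels_within_units(trials, rng)
    assert not np.array_equal(y, trials["class_label"].to_numpy())
    # each (exemplar, repetition) unit keeps exactly one trial per class
    df = trials.assign(perm=y)
    for _, unit in df.groupby(["exemplar", "repetition"]):
        assert sorted(unit["perm"]) == list(range(1, 8))


def test_permutation_null_properties(tiny_tmaps):
    by_sub = {s: tm for (s, t), tm in tiny_tmaps.items()}
    null = permutation_null(by_sub, n_perm=30, seed=11)
    assert null.n_perm == 30
    finite = np.all(np.isfinite(null.maps), axis=0)
    assert finite.any()
    # null centred at chance
    assert np.nanmean(null.maps) == pytest.approx(0.5, abs=0.01)
    # reproducible
    again = permutation_null(by_sub, n_perm=30, seed=11)
    np.testing.assert_array_equal(null.maps, again.maps)
    other = permutation_null(by_sub, n_perm=30, seed=12)
    assert not np.array_equal(null.maps, other.maps)


def test_voxelwise_p_add_one(small_grid):
    idx = np.arange(3)
    maps = np.array([[0.4, 0.6, 0.5],
                     [0.5, 0.7, 0.5],
                     [0.6, 0.4, 0.5]])
    null = NullDistribution(grid=small_grid, indices=idx, maps=maps, seed=0)
    obs = _mv(small_grid, idx, [0.55, 0.65, np.nan])
    p = voxelwise_p(obs, null)
    # add-one: (1 + #{null >= obs}) / (n_perm + 1)
    np.testing.assert_allclose(p.values[:2], [2 / 4, 2 / 4])
    assert np.isnan(p.values[2])
    assert p.values[np.isfinite(p.values)].min() >= 1 / 4


def test_estimate_fwhm_recovers_smoothness(rng):
    dims = (48, 48, 40)
    mask = np.ones(dims, dtype=bool)
    fields = smooth_noise(dims, fwhm_mm=6.0, voxel_mm=2.0, rng=rng, n=6)
    fwhm = estimate_fwhm(fields, mask, voxel_mm=2.0)
    assert fwhm.shape == (3,)
    np.testing.assert_allclose(fwhm, 6.0, rtol=0.10)


def test_estimate_fwhm_white_noise_warns(rng):
    # white noise is exactly at the d = 2v boundary; sampling noise puts some
    # axes over it, which must yield 0 + warning rather than a crash
    dims = (30, 30, 20)
    vol = rng.standard_normal(dims)
    import warnings as w
    with w.catch_warnings():
        w.simplefilter("ignore")
        fwhm = estimate_fwhm(vol, np.ones(dims, dtype=bool), 2.0)
    assert np.all(fwhm < 3.0)


def test_connectivity_structures():
    assert connectivity_structure("faces").sum() == 7
    assert connectivity_structure("faces+edges").sum() == 19
    assert connectivity_structure("faces+edges+corners").sum() == 27
    with pytest.raises(ValueError):
        connectivity_structure("diagonal")


def test_cluster_threshold_mc_monotone_in_smoothness():
    mask = np.ones((20, 20, 16), dtype=bool)
    t_smooth = cluster_threshold_mc(mask, 8.0, 2.0, n_iter=200, seed=0)
    t_rough = cluster_threshold_mc(mask, 0.0, 2.0, n_iter=200, seed=0)
    assert t_smooth > t_rough >= 1
    with pytest.raises(ValueError):
        cluster_threshold_mc(mask, 4.0, 2.0, n_iter=50)


def test_cluster_threshold_mc_binomial_oracle():
    """At FWHM 0 with 8-voxel masks, supra-threshold counts are Binomial;
    with alpha above the chance of any supra voxel the threshold is 1."""
    mask = np.zeros((20, 20, 16), dtype=bool)
    mask[:2, :2, :2] = True
    thr = cluster_threshold_mc(mask, 0.0, 2.0, voxel_p=0.01, alpha=0.5,
                               n_iter=400, seed=1)
    # P(any of 8 voxels supra) = 1 - 0.99^8 = 0.077 <= 0.5 -> m = 1
    assert thr == 1


def test_cluster_threshold_perm(small_grid, rng):
    idx = np.arange(small_grid.n_voxels)
    maps = rng.standard_normal((60, idx.size))
    null = NullDistribution(grid=small_grid, indices=idx, maps=maps, seed=0)
    thr = cluster_threshold_perm(null, voxel_p=0.05, alpha=0.05)
    assert thr >= 1
    # construction guarantee: thresholding each null map at its own rank p
    # and keeping clusters >= thr leaves at most alpha of the maps with a
    # surviving cluster
    from scipy.stats import rankdata
    pvals = rankdata(-maps, axis=0, method="max") / 60
    hits = 0
    for i in range(60):
        mv = MaskedVector(small_grid, idx, maps[i])
        tab, _ = extract_clusters(mv, pvals[i] < 0.05, min_size=thr)
        hits += len(tab) > 0
    assert hits / 60 <= 0.05
    with pytest.raises(ValueError):
        cluster_threshold_perm(NullDistribution(small_grid, idx,
                                                maps[:5], 0))


def flood_fill_clusters(vol):
    """Independent 6-connected flood fill oracle."""
    vol = np.asarray(vol, dtype=bool)
    seen = np.zeros_like(vol)
    comps = []
    for start in map(tuple, np.argwhere(vol)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)]:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (all(0 <= w[a] < vol.shape[a] for a in range(3))
                        and vol[w] and not seen[w]):
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return sorted(comps)


def test_extract_clusters_vs_flood_fill(rng):
    grid = VolumeGrid.isotropic((12, 11, 10), 2.0)
    for _ in range(5):
        vals = rng.standard_normal(grid.dims)
        mask = np.ones(grid.dims, dtype=bool)
        idx = np.arange(grid.n_voxels)
        mv = MaskedVector(grid, idx, vals.ravel(order="F"))
        thr = 1.0
        table, lab = extract_clusters(mv, thr, "faces", min_size=1)
        oracle = flood_fill_clusters(vals >= thr)
        # same component partition
        got = sorted(sorted(map(tuple, np.argwhere(lab == l)))
                     for l in table["label"])
        assert got == oracle
        # sizes sorted descending, peak is the max value in the cluster
        assert list(table["n_voxels"]) == sorted(table["n_voxels"],
                                                 reverse=True)
        for _, row in table.iterrows():
            comp = lab == row["label"]
            assert row["n_voxels"] == comp.sum()
            assert row["peak"] == pytest.approx(vals[comp].max())


def test_extract_clusters_min_size_and_cm():
    grid = VolumeGrid.isotropic((10, 10, 10), 2.0)
    vals = np.zeros(grid.dims)
    vals[2:5, 3, 3] = 2.0       # 3-voxel cluster
    vals[8, 8, 8] = 2.0         # singleton, dropped by min_size=2
    idx = np.arange(grid.n_voxels)
    mv = MaskedVector(grid, idx, vals.ravel(order="F"))
    table, lab = extract_clusters(mv, 1.0, min_size=2)
    assert len(table) == 1
    assert table.loc[0, "n_voxels"] == 3
    assert lab[8, 8, 8] == 0
    # unweighted centroid of (2,3,4),(3,3,3)... voxels -> (3,3,3) in vox
    cm_vox = np.array([3.0, 3.0, 3.0])
    cm_mm = cm_vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    np.testing.assert_allclose(
        table.loc[0, ["cm_x_mm", "cm_y_mm", "cm_z_mm"]].to_numpy(dtype=float),
        cm_mm)
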