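"""Group-level inference for searchlight accuracy maps.

Observed group maps are voxelwise averages of subject maps.  Significance is
assessed non-parametrically: class labels are permuted within subject (and
within each exemplar-repetition unit, which preserves the balance the
cross-validation folds rely on), the full searchlight is re-run, and subject
null maps sharing a permutation index are averaged into group null maps.
Voxelwise one-tailed p-values use the add-one rank estimator
``(1 + #{null >= observed}) / (n_perm + 1)``.

Cluster-extent correction follows the classical Monte-Carlo recipe: the
spatial smoothness (FWHM) of the null maps is estimated from first
differences, Gaussian fields of that smoothness are simulated inside the
mask, thresholded at the voxelwise p, and the (1 - alpha) quantile of the
maximum null cluster size gives the minimum cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .searchlight import SearchlightRankAccuracy, make_folds
from .volume import MaskedVector, VolumeGrid

__all__ = [
    "NullDistribution",
    "group_average",
    "permute_labels_within_units",
    "permutation_null",
    "voxelwise_p",
    "estimate_fwhm",
    "cluster_threshold_mc",
    "extract_clusters",
    "connectivity_structure",
]

_CONNECTIVITY = {"faces": 1, "faces+edges": 2, "faces+edges+corners": 3}


@dataclass
class NullDistribution:
    """Group accuracy maps under label permutation.

    ``maps`` is (n_perm, n_mask_voxels); each row averages all subjects'
    null maps computed with the SAME permutation index.
    """

    grid: VolumeGrid
    indices: np.ndarray
    maps: np.ndarray
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.maps.shape[0]


def group_average(subject_maps) -> MaskedVector:
    """Voxelwise mean of subject accuracy maps (NaN voxels propagate as
    missing: the mean is over the subjects with a value there)."""
    maps = list(subject_maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    first = maps[0]
    for m in maps[1:]:
        if not m.grid.matches(first.grid) or not np.array_equal(m.indices,
                                                                first.indices):
            raise ValueError("subject maps are on different grids/masks")
    stack = np.stack([m.values for m in maps])
    if np.isnan(stack).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(stack, axis=0)
    else:
        vals = stack.mean(axis=0)
    return MaskedVector(first.grid, first.indices, vals)


def permute_labels_within_units(trials, rng: np.random.Generator) -> np.ndarray:
    """Shuffle class labels within each (exemplar, repetition) unit.

    Each unit holds one trial per class, so the permuted labelling keeps
    every cross-validation fold balanced; labels remain exchangeable under
    the null hypothesis of no class information.
    """
    y = trials["class_label"].to_numpy().copy()
    units = list(zip(trials["exemplar"].to_numpy(),
                     trials["repetition"].to_numpy()))
    for u in set(units):
        sel = np.flatnonzero([x == u for x in units])
        y[sel] = rng.permutation(y[sel])
    return y


def permutation_null(tmaps_by_subject: dict, n_perm: int = 1000, seed: int = 0,
                     radius_mm: float = 6.0, min_sphere_frac: float = 0.5,
                     fold_strategy: str = "stimulus") -> NullDistribution:
    """Build the group null distribution for one task.

    Parameters
    ----------
    tmaps_by_subject : dict subject -> TMapStack (one task)
    n_perm : number of permutations (>= 100 recommended for p-value use)

    For each permutation index, every subject's labels are independently
    shuffled, the searchlight is re-run, and the subject null maps are
    averaged into one group null map.  Reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subjects = sorted(tmaps_by_subject)
    first = tmaps_by_subject[subjects[0]]
    n_vox = first.indices.size
    # one searchlight geometry per subject mask (shared here), reused across
    # permutations; folds are fixed by the design, not the labels
    sl = SearchlightRankAccuracy(first.grid, first.indices, radius_mm,
                                 min_sphere_frac, fold_strategy)
    folds = {s: make_folds(tmaps_by_subject[s].trials, fold_strategy)
             for s in subjects}
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(len(subjects))]
    maps = np.zeros((n_perm, n_vox))
    for p in range(n_perm):
        acc = np.zeros(n_vox)
        for si, s in enumerate(subjects):
            tm = tmaps_by_subject[s]
            y = permute_labels_within_units(tm.trials, rngs[si])
            if np.array_equal(y, tm.labels):
                warnings.warn(f"identity permutation drawn (perm {p}, "
                              f"subject {s})", stacklevel=2)
            sl.fit(tm.data, y, folds=folds[s])
            acc += sl.accuracy_map_.values
        maps[p] = acc / len(subjects)
    return NullDistribution(grid=first.grid, indices=first.indices, maps=maps,
                            seed=seed)


def voxelwise_p(observed: MaskedVector, null: NullDistribution) -> MaskedVector:
    """One-tailed add-one permutation p-value per voxel."""
    if null.maps.size == 0:
        raise ValueError("empty null distribution")
    if not np.array_equal(observed.indices, null.indices):
        raise ValueError("observed map and null are on different masks")
    obs = observed.values
    with np.errstate(invalid="ignore"):
        count = np.sum(null.maps >= obs[None, :], axis=0)
    p = (1.0 + count) / (null.n_perm + 1.0)
    p = np.where(np.isnan(obs), np.nan, p)
    return MaskedVector(observed.grid, observed.indices, p)


def estimate_fwhm(maps3d, mask: np.ndarray, voxel_mm) -> np.ndarray:
    """Per-axis FWHM (mm) from the first-difference variance estimator.

    For each axis, with v the voxel variance and d the variance of
    neighbouring-voxel differences (both voxels inside the mask), the
    Gaussian-equivalent kernel width is

        s^2 = -1 / (4 ln(1 - d / (2 v))),   FWHM = sqrt(8 ln 2) * s * voxel_mm.

    Estimates are averaged over the provided maps.  When d >= 2 v (rougher
    than white noise) the axis FWHM is reported as 0 with a warning.
    """
    maps3d = np.asarray(maps3d, dtype=float)
    if maps3d.ndim == 3:
        maps3d = maps3d[None]
    mask = np.asarray(mask, dtype=bool)
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    fwhms = np.zeros((maps3d.shape[0], 3))
    for mi, vol in enumerate(maps3d):
        vals = vol[mask]
        finite = np.isfinite(vals)
        v = np.var(vals[finite], ddof=1)
        if v == 0 or not np.isfinite(v):
            raise ValueError("constant (or all-missing) map: variance is zero")
        for ax in range(3):
            sl0 = [slice(None)] * 3
            sl1 = [slice(None)] * 3
            sl0[ax] = slice(0, -1)
            sl1[ax] = slice(1, None)
            pair = mask[tuple(sl0)] & mask[tuple(sl1)]
            diff = (vol[tuple(sl1)] - vol[tuple(sl0)])[pair]
            diff = diff[np.isfinite(diff)]
            if diff.size < 2:
                raise ValueError(f"mask too thin along axis {ax}")
            d = np.var(diff, ddof=1)
            ratio = d / (2.0 * v)
            if ratio >= 1.0:
                warnings.warn(f"axis {ax}: data rougher than white noise; "
                              "FWHM set to 0", stacklevel=2)
                fwhms[mi, ax] = 0.0
            else:
                s = np.sqrt(-1.0 / (4.0 * np.log(1.0 - ratio)))
                fwhms[mi, ax] = np.sqrt(8.0 * np.log(2.0)) * s * voxel_mm[ax]
    return fwhms.mean(axis=0)


def connectivity_structure(connectivity: str = "faces") -> np.ndarray:
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])


def cluster_threshold_mc(mask: np.ndarray, fwhm_mm, voxel_mm,
                         voxel_p: float = 0.05, alpha: float = 0.05,
                         n_iter: int = 1000, seed: int = 0,
                         connectivity: str = "faces") -> int:
    """Monte-Carlo minimum cluster size controlling family-wise error.

    Simulates ``n_iter`` Gaussian random fields of the given smoothness
    inside the mask, thresholds each at the one-tailed ``voxel_p`` level,
    and returns the smallest integer m such that the fraction of iterations
    whose largest cluster reaches m is at most ``alpha``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if not (0 < voxel_p < 1 and 0 < alpha <= 1):
        raise ValueError("voxel_p and alpha must be in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    fwhm_mm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm / np.sqrt(8 * np.log(2)) / voxel_mm
    zthr = stats.norm.isf(voxel_p)
    structure = connectivity_structure(connectivity)
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        field = rng.standard_normal(mask.shape)
        if np.any(sigma_vox > 0):
            field = ndimage.gaussian_filter(field, sigma=sigma_vox,
                                            mode="constant")
        vals = field[mask]
        field = (field - vals.mean()) / vals.std()
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = field[mask] >= zthr
        lab, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            max_sizes[it] = np.bincount(lab.ravel())[1:].max()
    # smallest m with P(max null cluster >= m) <= alpha
    for m in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= m) <= alpha:
            return m
    return int(max_sizes.max()) + 1


def cluster_threshold_perm(null: NullDistribution, voxel_p: float = 0.05,
                           alpha: float = 0.05,
                           connectivity: str = "faces") -> int:
    """Minimum cluster size from the permutation null maps themselves.

    Each null group map is thresholded at its own rank-based voxelwise p
    (``p_i(v) = #{j: M_j(v) >= M_i(v)} / n_perm``) and the maximum
    supra-threshold cluster size is recorded; the returned threshold is the
    smallest m whose exceedance fraction is at most ``alpha``.  Unlike a
    Gaussian-field simulation this inherits the true spatial autocorrelation
    of the accuracy maps, so the family-wise error of the thresholded
    observed map is controlled at ``alpha`` by construction.
    """
    from scipy.stats import rankdata

    M = null.maps
    n_perm = M.shape[0]
    if n_perm < 20:
        raise ValueError("need at least 20 permutations for a cluster null")
    finite = np.all(np.isfinite(M), axis=0)
    pvals = np.full(M.shape, np.nan)
    pvals[:, finite] = rankdata(-M[:, finite], axis=0,
                                method="max") / n_perm
    structure = connectivity_structure(connectivity)
    ref = MaskedVector(null.grid, null.indices,
                       np.zeros(null.indices.size))
    dims = null.grid.dims
    ijk = ref.ijk()
    max_sizes = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        supra = np.zeros(dims, dtype=bool)
        sel = pvals[i] < voxel_p
        sel &= np.isfinite(pvals[i])
        supra[tuple(ijk[sel].T)] = True
        lab, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            max_sizes[i] = np.bincount(lab.ravel())[1:].max()
    for m in range(1, int(max_sizes.max()) + 2):
        if np.mean(max_sizes >= m) <= alpha:
            return m
    return int(max_sizes.max()) + 1


def extract_clusters(stat_map: MaskedVector, keep, connectivity: str = "faces",
                     min_size: int = 1):
    """Label supra-threshold clusters and tabulate size, centre of mass, peak.

    Parameters
    ----------
    stat_map : MaskedVector of the statistic (accuracy) values.
    keep : either a boolean array aligned to the mask vector (voxels to
        keep), or a scalar threshold applied as ``value >= keep``.
    connectivity : {"faces", "faces+edges", "faces+edges+corners"}
    min_size : minimum cluster extent in voxels.

    Returns
    -------
    (table, label_vol) where table is a pandas DataFrame with columns
    label, n_voxels, cm_x_mm, cm_y_mm, cm_z_mm, peak (sorted by size,
    descending; labels renumbered 1..K) and label_vol is the labelled 3-D
    volume.  Centres of mass are unweighted voxel centroids mapped to mm.
    """
    import pandas as pd

    grid = stat_map.grid
    vol = np.full(grid.dims, np.nan)
    ijk = stat_map.ijk()
    vol[tuple(ijk.T)] = stat_map.values
    if np.isscalar(keep):
        keep_vec = stat_map.values >= keep
    else:
        keep_vec = np.asarray(keep, dtype=bool)
        if keep_vec.shape != stat_map.values.shape:
            raise ValueError("keep mask does not match the stat map")
    supra = np.zeros(grid.dims, dtype=bool)
    supra[tuple(ijk.T)] = keep_vec & np.isfinite(stat_map.values)
    structure = connectivity_structure(connectivity)
    lab, n_lab = ndimage.label(supra, structure=structure)
    rows = []
    for lbl in range(1, n_lab + 1):
        where = np.argwhere(lab == lbl)
        if where.shape[0] < min_size:
            lab[lab == lbl] = 0
            continue
        cm_vox = where.mean(axis=0)
        cm_mm = cm_vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
        peak = np.nanmax(vol[tuple(where.T)])
        rows.append((lbl, where.shape[0], *cm_mm, peak))
    rows.sort(key=lambda r: -r[1])
    relabel = np.zeros(n_lab + 1, dtype=int)
    table_rows = []
    for new, r in enumerate(rows, start=1):
        relabel[r[0]] = new
        table_rows.append((new, *r[1:]))
    lab = relabel[lab]
    table = pd.DataFrame(
        table_rows,
        columns=["label", "n_voxels", "cm_x_mm", "cm_y_mm", "cm_z_mm", "peak"],
    )
    return table, lab
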