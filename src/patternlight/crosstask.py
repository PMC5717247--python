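"""Cross-task accuracy transfer: each task probed inside the clusters the
other tasks define.

For every (defining task, cluster) x probe task cell, the probe task's
subject accuracy maps are averaged over the cluster voxels and across
subjects; significance is a one-tailed add-one rank test of the observed
group cluster mean against the probe task's permutation null reduced the
same way, Bonferroni-corrected over the whole family of cells.  The tone
task is probed in a separate single-probe family, mirroring the design of
testing whether vowel-defined clusters also carry tone information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import NullDistribution
from .volume import MaskedVector

__all__ = [
    "BonferroniSpec",
    "roi_mean_accuracy",
    "roi_permutation_p",
    "bonferroni_threshold",
    "cross_task_matrix",
    "spatial_overlap",
]


@dataclass(frozen=True)
class BonferroniSpec:
    """Family-wise alpha and comparison count; threshold = alpha / m."""

    alpha: float = 0.05
    m: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def threshold(self) -> float:
        return self.alpha / self.m


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha / m (display with 4 decimals)."""
    return BonferroniSpec(alpha, m).threshold


def _cluster_sel(cluster_mask, reference: MaskedVector) -> np.ndarray:
    """Boolean selector over the mask vector for a cluster given as either a
    vector-aligned boolean array or a 3-D volume mask."""
    cm = np.asarray(cluster_mask)
    if cm.shape == (reference.indices.size,):
        sel = cm.astype(bool)
    elif cm.shape == reference.grid.dims:
        sel = cm.astype(bool).ravel(order="F")[reference.indices]
    else:
        raise ValueError("cluster mask shape matches neither the mask vector "
                         "nor the grid")
    if not sel.any():
        raise ValueError("cluster does not intersect the analysis mask")
    return sel


def roi_mean_accuracy(subject_maps, cluster_mask):
    """Across-subject mean and standard error of cluster-mean accuracy.

    Each subject's accuracy map is averaged over the cluster voxels first;
    the mean and SE (sd / sqrt(n)) are then taken across subjects.
    """
    maps = list(subject_maps)
    sel = _cluster_sel(cluster_mask, maps[0])
    per_subject = np.array([np.nanmean(m.values[sel]) for m in maps])
    mean = float(per_subject.mean())
    n = len(per_subject)
    se = float(per_subject.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se


def roi_permutation_p(observed_mean: float, null: NullDistribution,
                      cluster_mask) -> float:
    """One-tailed add-one rank p of the observed cluster-mean accuracy
    against the null group maps reduced to the same cluster mean."""
    ref = MaskedVector(null.grid, null.indices, null.maps[0])
    sel = _cluster_sel(cluster_mask, ref)
    null_means = np.nanmean(null.maps[:, sel], axis=1)
    return float((1.0 + np.sum(null_means >= observed_mean))
                 / (null.n_perm + 1.0))


def cross_task_matrix(
    subject_maps_by_task: dict[str, list],
    cluster_masks_by_task: dict[str, list],
    nulls_by_task: dict[str, NullDistribution],
    probe_tasks=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full (defining task, cluster) x probe task accuracy-transfer matrix.

    ``cluster_masks_by_task`` maps each defining task to a list of
    ``(cluster_label, mask)`` pairs.  The Bonferroni family size is
    ``total clusters x n_probe_tasks`` (the defining task's own cell is part
    of the family).  Pass ``probe_tasks=["tone"]`` for the single-probe tone
    family.

    Returns a DataFrame with columns defining_task, cluster, probe_task,
    mean_accuracy, se, p, p_threshold, significant.
    """
    if probe_tasks is None:
        probe_tasks = sorted(subject_maps_by_task)
    n_clusters = sum(len(v) for v in cluster_masks_by_task.values())
    if n_clusters == 0:
        return pd.DataFrame(columns=["defining_task", "cluster", "probe_task",
                                     "mean_accuracy", "se", "p", "p_threshold",
                                     "significant"])
    spec = BonferroniSpec(alpha, n_clusters * len(probe_tasks))
    rows = []
    for def_task, clusters in cluster_masks_by_task.items():
        for label, cmask in clusters:
            for probe in probe_tasks:
                if probe not in subject_maps_by_task:
                    raise ValueError(f"no subject maps for probe task {probe!r}")
                mean, se = roi_mean_accuracy(subject_maps_by_task[probe], cmask)
                p = roi_permutation_p(mean, nulls_by_task[probe], cmask)
                rows.append((def_task, label, probe, mean, se, p,
                             spec.threshold, p < spec.threshold))
    return pd.DataFrame(rows, columns=["defining_task", "cluster", "probe_task",
                                       "mean_accuracy", "se", "p",
                                       "p_threshold", "significant"])


def spatial_overlap(cluster_masks_by_task: dict[str, np.ndarray]) -> pd.DataFrame:
    """Voxel counts of all pairwise and triple intersections of the tasks'
    combined cluster masks (3-D boolean volumes on a shared grid)."""
    tasks = sorted(cluster_masks_by_task)
    masks = {t: np.asarray(cluster_masks_by_task[t], dtype=bool) for t in tasks}
    shapes = {m.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ValueError("cluster masks are on different grids")
    rows = []
    for i, a in enumerate(tasks):
        for b in tasks[i + 1:]:
            rows.append((f"{a} & {b}", int((masks[a] & masks[b]).sum())))
    for i, a in enumerate(tasks):
        for j in range(i + 1, len(tasks)):
            for k in range(j + 1, len(tasks)):
                b, c = tasks[j], tasks[k]
                rows.append((f"{a} & {b} & {c}",
                             int((masks[a] & masks[b] & masks[c]).sum())))
    return pd.DataFrame(rows, columns=["intersection", "n_voxels"])
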