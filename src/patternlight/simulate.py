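"""Synthetic multi-subject datasets with known planted multivoxel signal.

The generator emulates the spatial structure of the study: an ellipsoidal
analysis mask standing in for the language-network mask, one compact
signal region per task (pairwise disjoint by default), and — optionally —
the tone task sharing its region with one vowel task, which is the structural
analogue of a region carrying both tone and vowel information.

Per-trial activity patterns are class templates planted inside the task's
region plus spatially smooth Gaussian noise everywhere; outside signal
regions the maps are pure smooth noise.  Smooth noise is white Gaussian
convolved with a Gaussian kernel of configurable FWHM and renormalized to
unit variance, emulating the combined acquisition and 4 mm preprocessing
smoothing without modelling scanner physics.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .design import DesignConfig, TONE_TASK, VOWEL_TASKS
from .volume import VolumeGrid, mask_indices

__all__ = [
    "PatternAtlas",
    "SignalParams",
    "TMapStack",
    "BoldRun",
    "make_pattern_atlas",
    "simulate_tmaps",
    "simulate_bold",
    "smooth_noise",
]

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class SignalParams:
    """Strength and structure of the planted signal.

    effect_amplitude
        Scale of the class-template patterns relative to the noise standard
        deviation; 0 disables the signal entirely.
    noise_sd
        Standard deviation of the smooth noise field (> 0).
    smoothness_fwhm_mm
        FWHM of the Gaussian kernel applied to the white noise (default 4 mm,
        the preprocessing smoothing of the emulated study).
    subject_pattern_consistency
        1 plants identical class patterns in every subject, 0 independent
        per-subject patterns; intermediate values mix the two with variance
        weights c and 1-c.
    """

    effect_amplitude: float = 1.0
    noise_sd: float = 1.0
    smoothness_fwhm_mm: float = 4.0
    subject_pattern_consistency: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("smoothness_fwhm_mm must be >= 0")
        if not 0.0 <= self.subject_pattern_consistency <= 1.0:
            raise ValueError("subject_pattern_consistency must be in [0, 1]")


@dataclass
class PatternAtlas:
    """Grid geometry, analysis mask and per-task signal regions."""

    grid: VolumeGrid
    mask: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    #: tasks that intentionally share voxels (e.g. tone planted in a vowel
    #: region); all other region pairs must be disjoint
    shared_tasks: frozenset = frozenset()

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.dims:
            raise ValueError("mask shape does not match grid")
        if not self.mask.any():
            raise ValueError("analysis mask is empty")
        tasks = list(self.regions)
        for t in tasks:
            reg = np.asarray(self.regions[t], dtype=bool)
            if not reg.any():
                raise ValueError(f"region for task {t!r} is empty")
            if np.any(reg & ~self.mask):
                raise ValueError(f"region for task {t!r} leaves the analysis mask")
            self.regions[t] = reg
        for i, a in enumerate(tasks):
            for b in tasks[i + 1:]:
                if {a, b} <= self.shared_tasks:
                    continue
                if np.any(self.regions[a] & self.regions[b]):
                    raise ValueError(f"regions {a!r} and {b!r} overlap")

    @property
    def mask_indices(self) -> np.ndarray:
        return mask_indices(self.mask)


def _ellipsoid_mask(dims) -> np.ndarray:
    """Ellipsoid inscribed in the grid box — a smooth stand-in brain mask."""
    grids = np.ogrid[tuple(slice(0, d) for d in dims)]
    centre = [(d - 1) / 2.0 for d in dims]
    semi = [max(d / 2.0 - 1.0, 1.0) for d in dims]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centre, semi))
    return r2 <= 1.0


def _grow_region(mask: np.ndarray, taken: np.ndarray, size: int,
                 rng: np.random.Generator, margin_vox: int = 0) -> np.ndarray:
    """Grow a compact connected blob of `size` voxels by breadth-first search.

    ``margin_vox`` keeps the blob at least that many voxels away from
    already-taken regions, so searchlight spheres centred near one region
    cannot reach another.
    """
    if margin_vox > 0 and taken.any():
        from scipy.ndimage import binary_dilation

        taken = binary_dilation(taken, iterations=margin_vox)
    free = mask & ~taken
    candidates = np.argwhere(free)
    if candidates.shape[0] < size:
        raise ValueError("infeasible packing: not enough free voxels")
    order = rng.permutation(candidates.shape[0])
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start_idx in order[: min(50, len(order))]:
        seed_vox = tuple(candidates[start_idx])
        region = np.zeros_like(mask)
        queue = deque([seed_vox])
        visited = {seed_vox}
        count = 0
        while queue and count < size:
            v = queue.popleft()
            if not free[v] or region[v]:
                continue
            region[v] = True
            count += 1
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if (all(0 <= w[a] < mask.shape[a] for a in range(3))
                        and w not in visited and free[w]):
                    visited.add(w)
                    queue.append(w)
        if count == size:
            return region
    raise ValueError("infeasible packing: could not grow a connected region")


def make_pattern_atlas(
    dims=(40, 48, 36),
    voxel_mm: float = 2.0,
    tasks=(TONE_TASK,) + VOWEL_TASKS,
    region_size_vox: int = 150,
    seed: int = 0,
    share_tone_with: str | None = "listening",
    margin_vox: int = 8,
) -> PatternAtlas:
    """Build an atlas with one signal region per task inside an ellipsoid mask.

    Regions are pairwise disjoint compact blobs; when ``share_tone_with``
    names a vowel task (and both tasks are present), the tone region is
    placed on exactly the same voxels as that task's region, so tone
    information is decodable inside a vowel-defined cluster.

    ``tasks`` may be empty (or ``region_size_vox`` 0) to get a mask-only atlas.
    """
    grid = VolumeGrid.isotropic(dims, voxel_mm)
    mask = _ellipsoid_mask(dims)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    regions: dict[str, np.ndarray] = {}
    shared: frozenset = frozenset()
    tasks = tuple(tasks)
    if region_size_vox > 0:
        taken = np.zeros_like(mask)
        grow_tasks = [t for t in tasks
                      if not (t == TONE_TASK and share_tone_with in tasks)]
        for t in grow_tasks:
            regions[t] = _grow_region(mask, taken, region_size_vox, rng,
                                      margin_vox)
            taken |= regions[t]
        if TONE_TASK in tasks and share_tone_with in tasks:
            regions[TONE_TASK] = regions[share_tone_with].copy()
            shared = frozenset({TONE_TASK, share_tone_with})
    return PatternAtlas(grid=grid, mask=mask, regions=regions, shared_tasks=shared)


@dataclass
class TMapStack:
    """Per-trial statistic patterns over masked voxels for one subject/task."""

    grid: VolumeGrid
    indices: np.ndarray          # mask voxel linear indices (Fortran order)
    data: np.ndarray             # (n_trials, n_mask_voxels)
    trials: pd.DataFrame         # aligned to data rows

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.trials), self.indices.size):
            raise ValueError("data shape does not match trials x mask size")

    @property
    def labels(self) -> np.ndarray:
        return self.trials["class_label"].to_numpy()


@dataclass
class BoldRun:
    """Simulated BOLD time series over masked voxels for one subject/task."""

    grid: VolumeGrid
    indices: np.ndarray
    data: np.ndarray             # (n_timepoints, n_mask_voxels)
    trials: pd.DataFrame
    tr_s: float
    #: decoded-event onsets in TR units within this run (lead-in included)
    onsets_tr: np.ndarray | None = None


def smooth_noise(dims, fwhm_mm: float, voxel_mm, rng: np.random.Generator,
                 n: int = 1) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian fields, shape (n, *dims)."""
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_mm
    out = rng.standard_normal((n,) + tuple(dims))
    if fwhm_mm > 0:
        for i in range(n):
            out[i] = gaussian_filter(out[i], sigma=sigma_vox, mode="constant")
        sd = out.std()
        if sd > 0:
            out /= sd
    return out


def _class_patterns(atlas: PatternAtlas, params: SignalParams, tasks, subjects,
                    n_classes: int):
    """Per (subject, task, class) planted pattern over the task's region voxels.

    A shared draw and a subject-specific draw are mixed with variance weights
    c and 1 - c, so consistency 1 gives identical patterns across subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 7]))
    c = params.subject_pattern_consistency
    patterns: dict[tuple[int, str, int], np.ndarray] = {}
    for task in tasks:
        if task not in atlas.regions:
            continue
        n_vox = int(atlas.regions[task].sum())
        shared = rng.standard_normal((n_classes, n_vox))
        for subject in subjects:
            own = rng.standard_normal((n_classes, n_vox))
            mixed = np.sqrt(c) * shared + np.sqrt(1.0 - c) * own
            for k in range(n_classes):
                patterns[(subject, task, k + 1)] = mixed[k]
    return patterns


def simulate_tmaps(trials: pd.DataFrame, atlas: PatternAtlas,
                   params: SignalParams) -> dict[tuple[int, str], TMapStack]:
    """Simulate per-trial statistic maps for every (subject, task) in `trials`.

    Each trial map is smooth noise over the analysis mask; trials of class c
    in a task with a signal region additionally receive
    ``effect_amplitude * pattern(subject, task, c)`` on the region voxels.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    tasks = list(trials["task"].unique())
    for t in tasks:
        if atlas.regions and t not in atlas.regions and params.effect_amplitude != 0:
            warnings.warn(f"task {t!r} has no signal region; pure noise simulated",
                          stacklevel=2)
    subjects = sorted(trials["subject"].unique())
    n_classes = int(trials["class_label"].max())
    idx = atlas.mask_indices
    region_vec = {
        t: atlas.regions[t].ravel(order="F")[idx] for t in atlas.regions
    }
    patterns = _class_patterns(atlas, params, tasks, subjects, n_classes)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 11]))
    out: dict[tuple[int, str], TMapStack] = {}
    for subject in subjects:
        for task in tasks:
            sub = trials[(trials["subject"] == subject)
                         & (trials["task"] == task)].reset_index(drop=True)
            if len(sub) == 0:
                continue
            noise = smooth_noise(atlas.grid.dims, params.smoothness_fwhm_mm,
                                 atlas.grid.voxel_mm, rng, n=len(sub))
            flat = noise.reshape(len(sub), -1, order="F")[:, idx] * params.noise_sd
            data = flat
            if task in region_vec and params.effect_amplitude != 0:
                rvec = region_vec[task]
                for i, row in sub.iterrows():
                    pat = patterns[(subject, task, int(row["class_label"]))]
                    data[i, rvec] += params.effect_amplitude * pat
            if not np.all(np.isfinite(data)):
                raise AssertionError("non-finite simulated values")
            out[(subject, task)] = TMapStack(grid=atlas.grid, indices=idx,
                                             data=data, trials=sub)
    return out


DEFAULT_HRF = np.array([0.0, 0.35, 0.9, 1.0, 0.6, 0.25, 0.08])
"""Per-TR response weights applied from the event onset (peak near 7.5 s at
TR 2.5 s); a plain boxcar ``[1.0]`` is useful for exact-recovery checks."""


def simulate_bold(trials: pd.DataFrame, atlas: PatternAtlas, params: SignalParams,
                  hrf: np.ndarray | None = None, tr_s: float = 2.5,
                  baseline: float = 100.0,
                  lead_in_s: float = 10.0) -> dict[tuple[int, str], BoldRun]:
    """Simulate BOLD runs whose decoded events carry the planted patterns.

    Each trial adds its class pattern (over the task region) times the
    response weights ``hrf`` starting at the trial's ``event_onset_s``,
    shifted by an initial ``lead_in_s`` rest period; the run extends one rest
    period past the last event.  The lead-in and tail leave the trial-wise
    FIR design of the run non-saturated (positive degrees of freedom) even
    when the modelled window spans the whole inter-trial interval.
    Overlapping response windows between consecutive events are rejected.
    The TR-unit onsets actually used are returned on each run.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    hrf = DEFAULT_HRF if hrf is None else np.asarray(hrf, dtype=float)
    idx = atlas.mask_indices
    region_vec = {t: atlas.regions[t].ravel(order="F")[idx] for t in atlas.regions}
    subjects = sorted(trials["subject"].unique())
    tasks = list(trials["task"].unique())
    n_classes = int(trials["class_label"].max())
    patterns = _class_patterns(atlas, params, tasks, subjects, n_classes)
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 13]))
    out: dict[tuple[int, str], BoldRun] = {}
    for subject in subjects:
        for task in tasks:
            sub = trials[(trials["subject"] == subject)
                         & (trials["task"] == task)].reset_index(drop=True)
            if len(sub) == 0:
                continue
            ev = sub["event_onset_s"].to_numpy() if "event_onset_s" in sub \
                else sub["onset_s"].to_numpy()
            on_tr = ev / tr_s
            lead = lead_in_s / tr_s
            if np.any(np.abs(on_tr - np.round(on_tr)) > 1e-9) \
                    or abs(lead - round(lead)) > 1e-9:
                raise ValueError("event onsets and lead-in must align to the "
                                 "TR grid")
            on_tr = np.round(on_tr).astype(int) + int(round(lead))
            if np.any(np.diff(np.sort(on_tr)) < len(hrf)):
                raise ValueError("overlapping response windows")
            n_t = int(on_tr.max()) + len(hrf) + int(round(8.0 / tr_s))
            noise = smooth_noise(atlas.grid.dims, params.smoothness_fwhm_mm,
                                 atlas.grid.voxel_mm, rng, n=n_t)
            series = noise.reshape(n_t, -1, order="F")[:, idx] * params.noise_sd
            series += baseline
            rvec = region_vec.get(task)
            if rvec is not None and params.effect_amplitude != 0:
                for i, row in sub.iterrows():
                    pat = patterns[(subject, task, int(row["class_label"]))]
                    t0 = on_tr[i]
                    for lag, w in enumerate(hrf):
                        series[t0 + lag, rvec] += w * params.effect_amplitude * pat
            out[(subject, task)] = BoldRun(grid=atlas.grid, indices=idx,
                                           data=series, trials=sub, tr_s=tr_s,
                                           onsets_tr=on_tr)
    return out
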