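"""Searchlight rank-accuracy classification with cosine-similarity templates.

The classifier is deliberately simple, matching common practice in auditory
decoding: each class is represented by the arithmetic mean of its training
patterns, a test pattern is compared to every template by cosine similarity,
and the score is the normalized rank of the true class,

    score = (C - r) / (C - 1),

with r = 1 for the most similar template.  Chance level is 0.5 for any
number of classes C >= 2; ties take the average rank.  Cross-validation is
leave-one-stimulus-out: each fold holds out one exemplar-repetition unit per
class (6 folds for 3 exemplars x 2 repetitions), so every test fold contains
one trial of each class.  The searchlight evaluates this classifier on the
voxels of a 6 mm sphere centred at every mask voxel and assigns the mean
cross-validated score to the centre.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin

from .volume import MaskedVector, VolumeGrid

__all__ = [
    "sphere_offsets",
    "make_folds",
    "class_templates",
    "rank_accuracy",
    "crossval_accuracy",
    "RankTemplateClassifier",
    "SearchlightRankAccuracy",
    "run_searchlight",
    "build_sphere_matrix",
]


def sphere_offsets(radius_mm: float, voxel_mm) -> np.ndarray:
    """Integer lattice offsets whose mm distance from the centre is <= radius.

    Returns an (n, 3) int array including (0, 0, 0).
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    voxel_mm = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,))
    if np.any(voxel_mm <= 0):
        raise ValueError("voxel size must be positive")
    max_off = np.floor(radius_mm / voxel_mm).astype(int)
    ranges = [np.arange(-m, m + 1) for m in max_off]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    dist2 = ((grid * voxel_mm) ** 2).sum(axis=1)
    return grid[dist2 <= radius_mm ** 2 + 1e-9]


def make_folds(trials: pd.DataFrame, strategy: str = "stimulus"):
    """Cross-validation folds over a trial table.

    strategy
        ``"stimulus"``: hold out one (exemplar, repetition) unit per class —
        the leave-one-stimulus-out default.  ``"trial"``: leave one trial out.
        ``"recording"``: hold out one exemplar with all its repetitions.

    Returns a list of (train_idx, test_idx) integer-array pairs; every trial
    is tested exactly once across folds.
    """
    n = len(trials)
    all_idx = np.arange(n)
    if strategy == "trial":
        folds = [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    elif strategy in ("stimulus", "recording"):
        if strategy == "stimulus":
            unit = list(zip(trials["exemplar"].to_numpy(),
                            trials["repetition"].to_numpy()))
        else:
            unit = list(trials["exemplar"].to_numpy())
        units = sorted(set(unit))
        folds = []
        unit = np.array([units.index(u) for u in unit])
        for u in range(len(units)):
            test = all_idx[unit == u]
            train = all_idx[unit != u]
            folds.append((train, test))
    else:
        raise ValueError(f"unknown fold strategy {strategy!r}")
    tested = np.concatenate([t for _, t in folds])
    if len(tested) != n or len(np.unique(tested)) != n:
        raise AssertionError("every trial must be tested exactly once")
    labels = trials["class_label"].to_numpy()
    classes = np.unique(labels)
    for train, _ in folds:
        if not set(classes) <= set(labels[train]):
            raise ValueError("fold leaves a class without training trials")
    return folds


def class_templates(train_patterns: np.ndarray, train_labels):
    """Arithmetic-mean template per class.

    Returns ``(classes, templates)`` with templates of shape
    (n_classes, n_features).  Zero-norm templates are flagged (cosine to them
    is undefined).
    """
    X = np.asarray(train_patterns, dtype=float)
    y = np.asarray(train_labels)
    classes = np.unique(y)
    templates = np.stack([X[y == c].mean(axis=0) for c in classes])
    norms = np.linalg.norm(templates, axis=1)
    if np.any(norms == 0):
        warnings.warn("zero-norm class template: cosine similarity undefined",
                      stacklevel=2)
    return classes, templates


def _cosine(x: np.ndarray, templates: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(x)
    nt = np.linalg.norm(templates, axis=1)
    if nx == 0 or np.any(nt == 0):
        raise ValueError("zero-norm vector: cosine similarity undefined")
    return templates @ x / (nt * nx)


def _rank_score(sims: np.ndarray, true_pos: int) -> float:
    """Normalized rank score from similarities; ties get the average rank."""
    C = sims.size
    s_true = sims[true_pos]
    higher = np.sum(sims > s_true)
    ties = np.sum(sims == s_true) - 1
    r = 1 + higher + 0.5 * ties
    return (C - r) / (C - 1)


def rank_accuracy(test_pattern: np.ndarray, templates: np.ndarray,
                  true_class, classes=None) -> float:
    """Rank-accuracy score of one test pattern against class templates.

    1 when the true class's template is the most cosine-similar, 0 when it is
    the least; chance is 0.5.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    if classes is None:
        classes = np.arange(1, templates.shape[0] + 1)
    classes = np.asarray(classes)
    pos = np.flatnonzero(classes == true_class)
    if pos.size != 1:
        raise ValueError(f"true class {true_class!r} not among classes")
    sims = _cosine(np.asarray(test_pattern, dtype=float), templates)
    return _rank_score(sims, int(pos[0]))


def crossval_accuracy(patterns: np.ndarray, labels, folds) -> float:
    """Mean rank accuracy over all held-out trials of all folds."""
    X = np.asarray(patterns, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    scores = []
    for train, test in folds:
        classes, templates = class_templates(X[train], y[train])
        for i in test:
            scores.append(rank_accuracy(X[i], templates, y[i], classes))
    return float(np.mean(scores))


class RankTemplateClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-mean-template classifier scored by cosine rank accuracy.

    ``fit`` stores per-class mean templates; ``predict`` returns the class of
    the most cosine-similar template; ``score`` returns the mean rank
    accuracy (chance 0.5), not plain accuracy.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        self.classes_, self.templates_ = class_templates(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        nt = np.linalg.norm(self.templates_, axis=1)
        nx = np.linalg.norm(X, axis=1)
        if np.any(nt == 0) or np.any(nx == 0):
            raise ValueError("zero-norm vector: cosine similarity undefined")
        return (X @ self.templates_.T) / np.outer(nx, nt)

    def predict(self, X):
        sims = self.decision_function(X)
        return self.classes_[np.argmax(sims, axis=1)]

    def rank_scores(self, X, y):
        """Per-sample rank-accuracy scores."""
        sims = self.decision_function(X)
        y = np.asarray(y)
        out = np.empty(len(y))
        for i in range(len(y)):
            pos = int(np.flatnonzero(self.classes_ == y[i])[0])
            out[i] = _rank_score(sims[i], pos)
        return out

    def score(self, X, y, sample_weight=None):
        return float(np.average(self.rank_scores(X, y), weights=sample_weight))


def build_sphere_matrix(grid: VolumeGrid, mask_idx: np.ndarray,
                        radius_mm: float, min_sphere_frac: float = 0.5):
    """Sparse centre x member matrix of sphere/mask intersections.

    Row i of the returned CSR matrix has ones at the mask voxels lying within
    ``radius_mm`` of mask voxel i.  ``valid`` marks centres whose sphere
    retains at least ``min_sphere_frac`` of the full sphere's voxels.
    """
    offs = sphere_offsets(radius_mm, grid.voxel_mm)
    dims = grid.dims
    n = mask_idx.size
    # map linear index -> position in the mask vector
    lut = -np.ones(grid.n_voxels, dtype=np.intp)
    lut[mask_idx] = np.arange(n)
    ijk = np.stack(np.unravel_index(mask_idx, dims, order="F"), axis=1)
    rows, cols = [], []
    for d in offs:
        nb = ijk + d
        ok = np.all((nb >= 0) & (nb < np.asarray(dims)), axis=1)
        lin = np.ravel_multi_index(nb[ok].T, dims, order="F")
        pos = lut[lin]
        inside = pos >= 0
        rows.append(np.flatnonzero(ok)[inside])
        cols.append(pos[inside])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    counts = np.asarray(A.sum(axis=1)).ravel()
    valid = counts >= min_sphere_frac * len(offs)
    return A, valid


class SearchlightRankAccuracy(BaseEstimator):
    """Whole-mask searchlight of the rank-template classifier.

    Parameters
    ----------
    grid, mask_idx
        Geometry: the sampling grid and the Fortran-order linear indices of
        the analysis-mask voxels.
    radius_mm : float, default 6
        Searchlight sphere radius.
    min_sphere_frac : float, default 0.5
        Minimum retained fraction of the full sphere for a centre to be
        evaluated; skipped centres get NaN.
    fold_strategy : {"stimulus", "trial", "recording"}

    After ``fit(X, y, trials=...)`` the fitted attributes are
    ``accuracy_map_`` (MaskedVector, NaN at skipped centres) and
    ``skipped_`` (boolean array over mask voxels).
    """

    def __init__(self, grid: VolumeGrid, mask_idx: np.ndarray,
                 radius_mm: float = 6.0, min_sphere_frac: float = 0.5,
                 fold_strategy: str = "stimulus", dtype=np.float64):
        self.grid = grid
        self.mask_idx = mask_idx
        self.radius_mm = radius_mm
        self.min_sphere_frac = min_sphere_frac
        self.fold_strategy = fold_strategy
        self.dtype = dtype

    def _sphere(self):
        if not hasattr(self, "_sphere_cache_"):
            A, valid = build_sphere_matrix(
                self.grid, np.asarray(self.mask_idx),
                self.radius_mm, self.min_sphere_frac,
            )
            self._sphere_cache_ = (A.astype(self.dtype), valid)
        return self._sphere_cache_

    def fit(self, X, y, trials: pd.DataFrame | None = None, folds=None):
        """Compute the per-voxel cross-validated accuracy map.

        X is (n_trials, n_mask_voxels); folds are derived from ``trials``
        with the configured strategy unless given explicitly.
        """
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y)
        if X.shape[1] != np.asarray(self.mask_idx).size:
            raise ValueError("pattern width does not match mask size")
        if folds is None:
            if trials is None:
                raise ValueError("provide either trials or folds")
            folds = make_folds(trials, self.fold_strategy)
        A, valid = self._sphere()
        n_vox = X.shape[1]
        # sphere-wise cosine similarities via sparse aggregation: dot products
        # and squared norms summed over sphere members, batched over folds
        fold_info, prod_cols, tmpl_rows = [], [], []
        for train, test in folds:
            classes, templates = class_templates(X[train], y[train])
            true_pos = np.array([int(np.flatnonzero(classes == y[i])[0])
                                 for i in test])
            prod = (X[test][:, None, :] * templates[None, :, :])
            prod_cols.append(prod.reshape(len(test) * len(classes), n_vox))
            tmpl_rows.append(templates)
            fold_info.append((len(test), len(classes), true_pos))
        X_sq = A @ (X ** 2).T                                  # (n_vox, n_trials)
        T_sq_all = A @ (np.concatenate(tmpl_rows) ** 2).T      # (n_vox, sum C)
        cross_all = A @ np.concatenate(prod_cols).T            # (n_vox, sum n*C)
        acc_sum = np.zeros(n_vox)
        n_scored = 0
        col_t = col_c = 0
        for (train, test), (n_test, C, true_pos) in zip(folds, fold_info):
            T_sq = T_sq_all[:, col_t:col_t + C]
            cross = cross_all[:, col_c:col_c + n_test * C].reshape(
                n_vox, n_test, C)
            col_t += C
            col_c += n_test * C
            with np.errstate(divide="ignore", invalid="ignore"):
                cos = cross / np.sqrt(T_sq[:, None, :]
                                      * X_sq[:, test][:, :, None])
            s_true = cos[:, np.arange(n_test), true_pos][:, :, None]
            higher = (cos > s_true).sum(axis=2)
            ties = (cos == s_true).sum(axis=2) - 1
            r = 1 + higher + 0.5 * ties
            acc_sum += ((C - r) / (C - 1)).sum(axis=1)
            n_scored += n_test
        acc = acc_sum / n_scored
        acc[~valid] = np.nan
        self.accuracy_map_ = MaskedVector(self.grid, np.asarray(self.mask_idx),
                                          acc)
        self.skipped_ = ~valid
        self.n_folds_ = len(folds)
        return self

    def fit_transform(self, X, y, **kwargs):
        return self.fit(X, y, **kwargs).accuracy_map_


def run_searchlight(tmaps, radius_mm: float = 6.0, min_sphere_frac: float = 0.5,
                    fold_strategy: str = "stimulus", labels=None,
                    sl: SearchlightRankAccuracy | None = None) -> MaskedVector:
    """Subject-level searchlight accuracy map from a TMapStack.

    ``labels`` overrides the stack's class labels (used for permutation
    nulls); ``sl`` lets callers reuse a fitted geometry (sphere matrix)
    across many runs.
    """
    if sl is None:
        sl = SearchlightRankAccuracy(tmaps.grid, tmaps.indices, radius_mm,
                                     min_sphere_frac, fold_strategy)
    y = tmaps.labels if labels is None else np.asarray(labels)
    sl.fit(tmaps.data, y, trials=tmaps.trials)
    return sl.accuracy_map_
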