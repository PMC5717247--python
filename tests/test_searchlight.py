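"""Searchlight geometry, rank-accuracy scoring, folds, estimator oracle."""

import numpy as np
import pandas as pd
import pytest

from patternlight.searchlight import (RankTemplateClassifier,
                                      SearchlightRankAccuracy,
                                      build_sphere_matrix, class_templates,
                                      crossval_accuracy, make_folds,
                                      rank_accuracy, run_searchlight,
                                      sphere_offsets)
from patternlight.simulate import SignalParams, simulate_tmaps
from patternlight.volume import MaskedVector


def brute_force_offsets(radius_mm, voxel_mm):
    r = int(np.ceil(radius_mm / min(np.broadcast_to(voxel_mm, 3))))
    out = []
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                d = np.array([i, j, k]) * np.broadcast_to(voxel_mm, 3)
                if np.dot(d, d) <= radius_mm ** 2 + 1e-12:
                    out.append((i, j, k))
    return sorted(out)


def test_sphere_offsets_123():
    offs = sphere_offsets(6.0, 2.0)
    assert len(offs) == 123
    assert sorted(map(tuple, offs)) == brute_force_offsets(6.0, 2.0)


@pytest.mark.parametrize("radius,vox", [(4.0, 2.0), (6.0, 3.0), (5.0, 2.5)])
def test_sphere_offsets_vs_lattice(radius, vox):
    offs = sorted(map(tuple, sphere_offsets(radius, vox)))
    assert offs == brute_force_offsets(radius, vox)


def test_rank_accuracy_hand_worked():
    # 3 classes; similarities to templates will be (1, 0, -1)-ordered
    templates = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    x = np.array([1.0, 0.0])
    # true class best: rank 1 of 3 -> (3-1)/2 = 1
    assert rank_accuracy(x, templates, 1) == 1.0
    # true class worst -> 0
    assert rank_accuracy(x, templates, 3) == 0.0
    # middle -> 0.5
    assert rank_accuracy(x, templates, 2) == 0.5
    with pytest.raises(ValueError):
        rank_accuracy(x, templates, 9)


def test_rank_accuracy_ties_average():
    templates = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    x = np.array([0.0, 1.0])
    # classes 2 and 3 tie for best: average rank 1.5 -> (3-1.5)/2 = 0.75
    assert rank_accuracy(x, templates, 2) == 0.75


def test_rank_accuracy_chance(rng):
    # random patterns: mean score near 0.5 regardless of class count
    scores = []
    templates = rng.standard_normal((7, 20))
    for _ in range(500):
        scores.append(rank_accuracy(rng.standard_normal(20), templates, 4,
                                    classes=np.arange(1, 8)))
    assert np.mean(scores) == pytest.approx(0.5, abs=0.03)


def _trials_frame(n_classes=3, n_ex=2, n_rep=2):
    rows = [(c, e, r) for c in range(1, n_classes + 1)
            for e in range(1, n_ex + 1) for r in range(1, n_rep + 1)]
    return pd.DataFrame(rows, columns=["class_label", "exemplar", "repetition"])


def test_make_folds_stimulus():
    trials = _trials_frame(3, 3, 2)
    folds = make_folds(trials, "stimulus")
    assert len(folds) == 6  # one per (exemplar, repetition) unit
    y = trials["class_label"].to_numpy()
    tested = []
    for train, test in folds:
        assert len(test) == 3  # one trial per class in each test fold
        assert sorted(y[test]) == [1, 2, 3]
        tested.extend(test)
    assert sorted(tested) == list(range(len(trials)))


def test_make_folds_other_strategies():
    trials = _trials_frame(3, 3, 2)
    assert len(make_folds(trials, "trial")) == len(trials)
    assert len(make_folds(trials, "recording")) == 3
    with pytest.raises(ValueError):
        make_folds(trials, "bogus")


def test_make_folds_rejects_missing_class():
    # a class present in only one unit leaves a fold without training trials
    trials = _trials_frame(2, 1, 1)
    with pytest.raises(ValueError):
        make_folds(trials, "stimulus")


def test_class_templates_and_classifier(rng):
    centers = np.array([[4.0, 0.0, 0], [0, 4.0, 0], [0, 0, 4.0]])
    X = np.repeat(centers, 10, axis=0) + 0.1 * rng.standard_normal((30, 3))
    y = np.repeat([1, 2, 3], 10)
    classes, templates = class_templates(X, y)
    np.testing.assert_array_equal(classes, [1, 2, 3])
    np.testing.assert_allclose(templates, centers, atol=0.2)
    clf = RankTemplateClassifier().fit(X, y)
    assert clf.score(X, y) == 1.0
    np.testing.assert_array_equal(clf.predict(centers), [1, 2, 3])
    assert clf.decision_function(X).shape == (30, 3)


def test_crossval_accuracy_separable():
    trials = _trials_frame(2, 2, 1)
    X = np.array([[5.0, 0], [5.0, 0], [0, 5.0], [0, 5.0]])
    X = X[np.argsort(trials.index)]  # aligned rows
    folds = make_folds(trials, "stimulus")
    acc = crossval_accuracy(X + 0.01, trials["class_label"], folds)
    assert acc == 1.0


def test_build_sphere_matrix(tiny_atlas):
    A, valid = build_sphere_matrix(tiny_atlas.grid, tiny_atlas.mask_indices,
                                   radius_mm=6.0, min_sphere_frac=0.5)
    n = tiny_atlas.mask_indices.size
    assert A.shape == (n, n)
    # membership is symmetric and includes the centre itself
    assert (A != A.T).nnz == 0
    assert np.all(A.diagonal() == 1)
    counts = np.asarray(A.sum(axis=1)).ravel()
    assert counts.max() <= 123
    np.testing.assert_array_equal(valid, counts >= 0.5 * 123)
    assert valid.any() and not valid.all()


def test_searchlight_matches_per_centre_oracle(tiny_atlas, tiny_tmaps):
    """Vectorized searchlight equals a literal per-centre loop of the
    rank-template cross-validation."""
    tm = tiny_tmaps[(1, "listening")]
    sl = SearchlightRankAccuracy(tiny_atlas.grid, tiny_atlas.mask_indices,
                                 radius_mm=5.0)
    sl.fit(tm.data, tm.labels, trials=tm.trials)
    acc = sl.accuracy_map_.values
    A, valid = build_sphere_matrix(tiny_atlas.grid, tiny_atlas.mask_indices,
                                   radius_mm=5.0, min_sphere_frac=0.5)
    folds = make_folds(tm.trials, "stimulus")
    A = A.tocsr()
    rng = np.random.default_rng(0)
    centres = rng.choice(np.flatnonzero(valid), size=25, replace=False)
    for c in centres:
        vox = A[c].indices
        ref = crossval_accuracy(tm.data[:, vox], tm.labels, folds)
        assert acc[c] == pytest.approx(ref, abs=1e-12)
    assert np.isnan(acc[~valid]).all()
    assert sl.skipped_.sum() == (~valid).sum()


def test_searchlight_above_chance_in_region(tiny_atlas, tiny_tmaps):
    tm = tiny_tmaps[(1, "listening")]
    sl = SearchlightRankAccuracy(tiny_atlas.grid, tiny_atlas.mask_indices)
    sl.fit(tm.data, tm.labels, trials=tm.trials)
    idx = tiny_atlas.mask_indices
    region = tiny_atlas.regions["listening"]
    rvec = region.ravel(order="F")[idx]
    # centres within one radius of the region also see signal voxels, so the
    # chance check uses only voxels beyond that rim
    from scipy.ndimage import binary_dilation
    rim = binary_dilation(region, iterations=3).ravel(order="F")[idx]
    inside = np.nanmean(sl.accuracy_map_.values[rvec])
    far = np.nanmean(sl.accuracy_map_.values[~rim])
    assert inside > 0.7
    assert abs(far - 0.5) < 0.1


def test_run_searchlight_wrapper(tiny_atlas, tiny_tmaps):
    tm = tiny_tmaps[(1, "listening")]
    mv = run_searchlight(tm)
    assert isinstance(mv, MaskedVector)
    assert mv.n == tiny_atlas.mask_indices.size
    # label override changes the map (permutation-null pathway)
    rng = np.random.default_rng(1)
    mv_perm = run_searchlight(tm, labels=rng.permutation(tm.labels))
    assert not np.array_equal(mv.values, mv_perm.values)
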