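"""Per-trial response estimation with an FIR design, plus univariate stats.

Runs are normalized to percent of the voxel's temporal mean, then each trial
gets one unit-impulse regressor per post-onset TR (an FIR basis; with
TR-locked onsets this is equivalent to a tent/piecewise-linear deconvolution
basis).  Ordinary least squares yields per-trial coefficients and T-values
at every time bin; the per-trial pattern used downstream is the T-value at a
selected latency (default bin index 3, i.e. 7.5 s after the event at a 2.5 s
TR, targeting the response peak while avoiding preparatory activity).

Nuisance regressors default to Legendre polynomial trends up to order 2 per
run; motion or other confound columns can be appended by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normalize_run",
    "build_fir_design",
    "fit_glm",
    "FIRTrialEstimator",
    "ttest_vs_zero",
    "fdr_bh",
    "GLMResult",
]


def normalize_run(series: np.ndarray, eps: float = 1e-12):
    """Divide each voxel's time course by its temporal mean.

    Parameters
    ----------
    series : (n_timepoints, n_voxels) array

    Returns
    -------
    normalized : array of the same shape; voxels whose temporal mean is zero
        (within ``eps``) are left at zero and reported.
    bad : boolean array marking the excluded zero-mean voxels.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be 2-D (time x voxels)")
    mean = series.mean(axis=0)
    bad = np.abs(mean) <= eps
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-mean voxels excluded from "
                      "normalization", stacklevel=2)
    safe = np.where(bad, 1.0, mean)
    out = series / safe
    out[:, bad] = 0.0
    return out, bad


def legendre_trends(n_timepoints: int, order: int) -> np.ndarray:
    """Legendre polynomials of degree 0..order sampled on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_timepoints)
    cols = [legendre.legval(x, [0] * d + [1]) for d in range(order + 1)]
    return np.stack(cols, axis=1)


def build_fir_design(onsets_tr, run_len_tr: int, n_tents: int = 5,
                     nuisance: np.ndarray | None = None,
                     trend_order: int | None = 2):
    """FIR design matrix: one unit regressor per (trial, post-onset TR bin).

    Parameters
    ----------
    onsets_tr : sequence of int
        Trial event onsets in TR units (must lie within the run).
    run_len_tr : int
        Run length in TRs.
    n_tents : int
        Number of post-onset bins modelled per trial (>= 3).
    nuisance : optional (run_len_tr, k) array of confound columns.
    trend_order : polynomial trend order appended as nuisance (None to skip).

    Returns
    -------
    design : (run_len_tr, n_trials*n_tents + n_nuisance) array
    labels : list of column labels; trial columns are ``("trial", i, lag)``,
        nuisance columns ``("nuisance", name)``.
    """
    onsets_tr = np.asarray(onsets_tr, dtype=int)
    if n_tents < 3:
        raise ValueError("n_tents must be >= 3")
    if np.any(onsets_tr < 0) or np.any(onsets_tr + n_tents > run_len_tr):
        raise ValueError("trial response window extends beyond the run")
    cols, labels = [], []
    for i, t0 in enumerate(onsets_tr):
        for lag in range(n_tents):
            col = np.zeros(run_len_tr)
            col[t0 + lag] = 1.0
            cols.append(col)
            labels.append(("trial", i, lag))
    if trend_order is not None:
        trends = legendre_trends(run_len_tr, trend_order)
        for d in range(trends.shape[1]):
            cols.append(trends[:, d])
            labels.append(("nuisance", f"legendre{d}"))
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            labels.append(("nuisance", f"extra{j}"))
    design = np.stack(cols, axis=1)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {design.shape[1]})"
        )
    return design, labels


@dataclass
class GLMResult:
    """OLS estimates for every design column at every voxel."""

    coef: np.ndarray      # (n_regressors, n_voxels)
    tval: np.ndarray      # (n_regressors, n_voxels)
    dof: int
    labels: list


def fit_glm(series: np.ndarray, design: np.ndarray, labels=None) -> GLMResult:
    """Ordinary least squares fit of `design` to every voxel's time course.

    T-values are coefficient / SE with SE from the residual variance and
    ``dof = n_timepoints - n_regressors``.
    """
    series = np.asarray(series, dtype=float)
    design = np.asarray(design, dtype=float)
    n_t, n_reg = design.shape
    if series.shape[0] != n_t:
        raise ValueError("series and design row counts differ")
    dof = n_t - n_reg
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({dof})")
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = xtx_inv @ design.T @ series
    resid = series - design @ coef
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, np.nan)
    if labels is None:
        labels = list(range(n_reg))
    return GLMResult(coef=coef, tval=tval, dof=dof, labels=list(labels))


class FIRTrialEstimator(BaseEstimator):
    """Per-trial response estimator (scikit-learn style).

    Fits the FIR GLM to a normalized run and exposes the per-trial T-value
    (or coefficient) pattern at the selected post-onset bin.

    Parameters
    ----------
    n_tents : int, default 5
        Post-onset TR bins modelled per trial.
    select_index : int, default 3
        Bin whose estimate becomes the trial's pattern; its latency is
        ``select_index * tr_s`` seconds (7.5 s at the default 2.5 s TR).
    trend_order : int, default 2
        Legendre trend order included as nuisance.
    use_tvalues : bool, default True
        Use T-values (not raw coefficients) as the per-trial patterns.
    normalize : bool, default True
        Apply mean normalization before fitting.
    """

    def __init__(self, n_tents: int = 5, select_index: int = 3,
                 trend_order: int = 2, use_tvalues: bool = True,
                 normalize: bool = True):
        self.n_tents = n_tents
        self.select_index = select_index
        self.trend_order = trend_order
        self.use_tvalues = use_tvalues
        self.normalize = normalize

    def fit(self, series: np.ndarray, onsets_tr, tr_s: float = 2.5,
            nuisance: np.ndarray | None = None):
        """Fit the run; `series` is (n_timepoints, n_voxels)."""
        if self.select_index >= self.n_tents:
            raise ValueError("select_index must be < n_tents")
        series = np.asarray(series, dtype=float)
        if self.normalize:
            series, self.excluded_voxels_ = normalize_run(series)
        else:
            self.excluded_voxels_ = np.zeros(series.shape[1], dtype=bool)
        design, labels = build_fir_design(
            onsets_tr, series.shape[0], self.n_tents, nuisance=nuisance,
            trend_order=self.trend_order,
        )
        res = fit_glm(series, design, labels)
        n_trials = len(onsets_tr)
        rows = [labels.index(("trial", i, self.select_index))
                for i in range(n_trials)]
        src = res.tval if self.use_tvalues else res.coef
        self.trial_patterns_ = src[rows]
        self.trial_coefs_ = res.coef[rows]
        self.glm_ = res
        self.latency_s_ = self.select_index * tr_s
        return self

    def transform(self, series=None):
        """Return the fitted (n_trials, n_voxels) pattern matrix."""
        if not hasattr(self, "trial_patterns_"):
            raise RuntimeError("estimator is not fitted")
        return self.trial_patterns_


def ttest_vs_zero(values: np.ndarray):
    """Voxelwise one-sample two-tailed t-test of subject values against zero.

    Parameters
    ----------
    values : (n_subjects, n_voxels) array, n_subjects >= 2.

    Returns
    -------
    t, p : arrays of length n_voxels; zero-variance voxels get NaN in both
    (flagged with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance voxels; p undefined",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(values, 0.0, axis=0)
    t = np.where(zero_var, np.nan, t)
    p = np.where(zero_var, np.nan, p)
    return np.squeeze(t), np.squeeze(p)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)
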