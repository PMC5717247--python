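# Methods

This note documents the statistical methods implemented by `patternlight`
and the reasoning behind the package's defaults. The pipeline emulates a
searchlight MVPA study of vowel processing across four auditory tasks and
validates the whole inference chain on synthetic data with known planted
signal.

## Stimuli and psychoacoustics

Pure tones are placed on canonical centres of integer Bark critical bands so
that each tone occupies a single auditory filter. The continuous conversion
is Traunmüller's approximation `z = 26.81 f / (1960 + f) − 0.53` with its
algebraic inverse; integer bands 1–24 map to the Zwicker table of centre
frequencies (band 11 → 1370 Hz). The published tone set uses the Bark bands
recorded in the vowel formant table ({5, 8, 11, 13, 14, 15, 16} → {450, 840,
1370, 1850, 2150, 2500, 2900} Hz). An alternative `f1_bins` strategy bins an
explicit frequency range into `n` equally spaced values, rounds each to the
nearest integer band, and deduplicates; the range is an explicit argument
because the literal min/max of the mean-F1 column does not span the
published band set.

## Design

Each (subject, task) run presents 7 classes. Vowel tasks use 7 vowels × 3
recorded exemplars × 2 repetitions = 42 trials (21 distinct stimuli).
Tones have no exemplar dimension, so the tone task uses 7 tones × 6
repetitions = 42 trials, keeping every sound equally represented.
Perceptual trials last 2 s stimulus + 8 s rest (10 s); imagery and
production trials add an 8 s maintenance period and a 2 s execution window
(20 s), and the decoded event is the execution onset. All durations are
multiples of the 2.5 s TR, so event onsets are TR-locked by construction.

## Synthetic data generator

The atlas is an ellipsoid mask with one compact, breadth-first-grown signal
region per task. Disjoint regions keep a margin (default 8 voxels) from one
another so that a searchlight sphere centred near one region cannot reach
another; with smaller margins, smooth-noise excursions can bridge a true
cluster into a neighbouring planted region. The tone region is placed on
exactly the listening region's voxels, planting the cross-task sharing the
transfer analysis is meant to detect.

Noise is white Gaussian smoothed to 4 mm FWHM and renormalized to unit
variance. Each class gets a planted pattern on its task's region voxels; a
shared draw and a subject-specific draw are mixed with variance weights `c`
and `1 − c` (`subject_pattern_consistency`, default 1). In `tmap` mode the
per-trial maps are noise plus `effect_amplitude ×` pattern. In `bold` mode
the patterns are convolved with a fixed response shape into a baseline-100
time series; runs start with a 10 s lead-in rest, and the pipeline truncates
the response window and FIR tent count to the trial duration (perception:
4 tents — the selected bin 3 is the last; imagery/production: 5 tents), so
the trial-wise FIR design stays full-rank with positive degrees of freedom.

## Per-trial estimation

Runs are normalized to percent of each voxel's temporal mean. The design
has one unit-impulse regressor per (trial, post-onset TR bin) — with
TR-locked onsets this equals a tent/deconvolution basis — plus Legendre
trends up to order 2. OLS T-values at bin 3 (7.5 s after the decoded event
at TR 2.5 s) form the per-trial patterns.

## Searchlight decoding

For each mask voxel, the sphere of 6 mm radius (123 voxels at 2 mm
isotropic) intersected with the mask feeds a rank-template classifier:
per-class mean templates from the training trials, cosine similarity of the
held-out trial to each template, and the normalized rank of the true class,
`(C − r)/(C − 1)` with average ranks on ties — 1 when the true class is most
similar, 0 when least, chance 0.5 for any class count. Cross-validation
holds out one (exemplar, repetition) unit per fold (leave-one-stimulus-out:
6 folds, each testing one trial per class). Centres whose sphere retains
less than half the full sphere are skipped (NaN). The implementation
evaluates all centres at once through a sparse sphere-membership matrix and
is verified against a literal per-centre loop.

## Group inference

Subject accuracy maps are averaged voxelwise. The null distribution
shuffles each subject's class labels independently *within each (exemplar,
repetition) unit* — each unit holds one trial per class, so permuted
labellings keep every fold balanced and remain exchangeable under the null —
recomputes the searchlight, and averages subjects into a group null map
(default 1000 permutations). Voxelwise significance is the one-tailed
add-one rank `p = (1 + #{null ≥ obs}) / (n_perm + 1)`.

### Cluster-extent correction

Voxels below `voxel_p` (default 0.05) are clustered (face connectivity) and
kept if they reach a minimum size controlling family-wise error at
`cluster_alpha` (default 0.05). Two threshold derivations are provided:

* **`permutation` (default).** Each null group map is thresholded at its own
  rank-based voxelwise p and the maximum supra-threshold cluster size
  recorded; the threshold is the smallest size whose exceedance fraction is
  ≤ alpha. This inherits the true spatial autocorrelation of searchlight
  accuracy maps, so the correction is calibrated by construction. In a
  60-replicate null study the observed family-wise error rate was 0.067
  (nominal 0.05, binomial bound 0.106) with grand-mean accuracy 0.499.
* **`mc`.** Monte-Carlo simulation of Gaussian random fields inside the mask
  at the smoothness estimated from the null maps (the classic
  3dClustSim-style correction). The per-axis FWHM comes from the
  first-difference variance estimator `s² = −1/(4 ln(1 − d/2v))`,
  `FWHM = √(8 ln 2)·s·voxel_mm`. **Caveat:** searchlight accuracy maps have
  heavier-tailed spatial autocorrelation than a Gaussian field of matched
  curvature (sphere overlap plus within-subject trial reuse); in the same
  null study the Gaussian threshold was ~46 voxels where the empirical null
  95th-percentile max cluster was ~114, inflating the family-wise error to
  ~0.18. This reproduces a known weakness of Gaussian-field cluster
  corrections on non-Gaussian autocorrelation; non-Gaussian (mixed ACF)
  smoothness models are out of scope, hence the permutation-based default.

Univariate group statistics (one-sample t-test of trial-mean patterns
against zero with Benjamini–Hochberg FDR) are produced alongside as a
baseline map.

## Cross-task transfer

For every (defining task, cluster) × probe task cell, the probe task's
subject accuracy maps are averaged over the cluster voxels, and the group
cluster mean is tested against the probe task's permutation null reduced the
same way (one-tailed add-one rank). The Bonferroni family is all clusters ×
all probe tasks: with 6 clusters × 3 vowel probes the threshold is
0.05/18 ≈ 0.0028; the tone probe forms its own single-probe family
(6 clusters → 0.05/6 ≈ 0.0083). A spatial-overlap table of the tasks'
cluster masks accompanies the matrices.

## Validation strategy

The acceptance suite (`tests/test_acceptance.py`) checks, at desk scale:
recomputable study constants; oracle equivalences (sphere lattice
enumeration, GLM normal equations to 1e-9, flood-fill clustering,
hand-worked rank scores); null-pipeline calibration (grand-mean accuracy
0.5 ± 0.01 and family-wise error within the binomial bound over 30 null
replicates; all-null FDR within `q + 2·SE`); parameter recovery (planted
regions recovered with Dice > 0.5 per task, vowel-task cluster overlap
Jaccard < 0.1, transfer significance exactly where sharing was planted);
and FWHM-estimator recovery of a known 6 mm smoothness within 10%.

The recovery scenario (3 subjects, 30×30×16 grid, 400-voxel regions,
amplitude 0.5, 250 permutations) was fixed from development pre-studies of
detectability before the acceptance tests were written; with 250
permutations the smallest attainable transfer p, 1/251 ≈ 0.004, stays below
the family thresholds.
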