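# patternlight

Searchlight multivoxel pattern analysis (MVPA) of a slow event-related
auditory fMRI experiment — tone perception, vowel listening, vowel imagery
and vowel production — exercised end to end on a synthetic-data generator
with planted, recoverable signal.

The package implements the full inference chain of a vowel-decoding study:

* **Psychoacoustics** — Traunmüller Hz↔Bark conversion, the canonical
  Zwicker critical-band centres, the vowel formant table, and the pure-tone
  stimulus-set construction (`patternlight.bark`).
* **Design** — randomized, TR-locked trial schedules: 7 vowels × 3 recorded
  exemplars × 2 repetitions = 42 trials per vowel task; 7 tones × 6
  repetitions (`patternlight.design`).
* **Synthetic data** — ellipsoid brain mask, compact disjoint per-task signal
  regions (the tone region intentionally shared with listening), smooth
  Gaussian noise, and per-trial statistic maps or BOLD time series with
  planted class patterns (`patternlight.simulate`).
* **Per-trial GLM** — mean normalization, per-trial FIR/tent deconvolution
  with Legendre trends, T-value patterns at the 7.5 s latency bin
  (`patternlight.glm`, `FIRTrialEstimator`).
* **Searchlight decoding** — 6 mm spheres (123 voxels at 2 mm), per-class
  mean templates, cosine similarity, normalized rank-accuracy scoring
  (chance 0.5), leave-one-stimulus-out cross-validation
  (`patternlight.searchlight`, `SearchlightRankAccuracy`,
  `RankTemplateClassifier`).
* **Group inference** — label permutations within balanced stimulus units,
  group null maps, add-one voxelwise p-values, first-difference FWHM
  estimation, and cluster-extent correction (permutation-based by default,
  Gaussian-field Monte Carlo optional) (`patternlight.inference`).
* **Cross-task transfer** — each task's accuracy probed inside the clusters
  other tasks define, Bonferroni-corrected over the whole family
  (`patternlight.crosstask`).
* **Pipeline + CLI** — staged orchestration with YAML configs, deterministic
  seeding, NIfTI/TSV artifacts and a hash manifest (`patternlight.pipeline`,
  `patternlight` console command).

## Quick start

```bash
# run the full pipeline at desk scale into ./results/demo
patternlight all -o results/demo --seed 7

# or stage by stage
patternlight simulate   -c config.yaml -o results/run
patternlight searchlight -c config.yaml -o results/run
patternlight infer      -c config.yaml -o results/run
patternlight crosstask  -c config.yaml -o results/run
patternlight report     -o results/run
```

From Python:

```python
from patternlight import PipelineConfig, run_pipeline
from patternlight.design import DesignConfig
from patternlight.simulate import SignalParams

cfg = PipelineConfig(
    design=DesignConfig(n_subjects=3),
    signal=SignalParams(effect_amplitude=0.5),
    dims=(30, 30, 16), region_size_vox=400, n_perm=250, seed=7,
)
run_pipeline(cfg, "results/demo")
```

Each run writes its resolved `config.yaml`, trial table, masks and region
volumes, per-trial maps, subject accuracy maps, group/p/cluster volumes,
cluster tables, cross-task transfer matrices, a plain-text report and a
`manifest.json` with SHA-256 hashes of every artifact; a rerun with the same
configuration is bit-identical.

## Testing

```bash
pytest -q                        # full suite incl. acceptance (~15-20 min)
pytest -q --ignore=tests/test_acceptance.py   # fast unit suite (~2 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion: printed
study quantities, oracle equivalences (sphere lattice, GLM normal equations,
flood-fill clustering, hand-worked rank scores), null-pipeline calibration
(chance-level accuracy, family-wise error, FDR), parameter recovery of
planted signal (Dice, overlap, transfer flags), and FWHM-estimator recovery.

See `docs/methods.md` for the statistical methods and the design decisions
behind the defaults.
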