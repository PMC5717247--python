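"""End-to-end orchestration: simulate -> estimate -> searchlight -> group
inference -> cross-task transfer -> report.

Every run writes its resolved configuration, a timestamped log and a JSON
manifest with the master seed and content hashes of all artifacts, so a rerun
with the same configuration is bit-identical.  Stages can be run separately
(each loads what it needs from the results directory) or composed with
:func:`run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crosstask as ct
from . import inference as inf
from .design import DesignConfig, TONE_TASK, VOWEL_TASKS, make_design, \
    read_trial_table, write_trial_table
from .glm import FIRTrialEstimator, fdr_bh, ttest_vs_zero
from .searchlight import SearchlightRankAccuracy, make_folds
from .simulate import DEFAULT_HRF, PatternAtlas, SignalParams, TMapStack, \
    make_pattern_atlas, simulate_bold, simulate_tmaps
from .volume import MaskedVector, apply_mask, read_series, read_volume, \
    unflatten, write_series, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

log = logging.getLogger("patternlight")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run (defaults are desk scale)."""

    design: DesignConfig = field(default_factory=lambda: DesignConfig(n_subjects=4))
    signal: SignalParams = field(default_factory=SignalParams)
    # atlas geometry
    dims: tuple[int, int, int] = (40, 48, 36)
    voxel_mm: float = 2.0
    region_size_vox: int = 150
    region_margin_vox: int = 8
    share_tone_with: str | None = "listening"
    # analysis
    data_mode: str = "tmap"            # "tmap" or "bold"
    radius_mm: float = 6.0
    min_sphere_frac: float = 0.5
    fold_strategy: str = "stimulus"
    n_perm: int = 1000
    mc_iterations: int = 1000          # 10000 at full scale
    cluster_method: str = "permutation"  # or "mc" (Gaussian-field Monte Carlo)
    voxel_p: float = 0.05
    cluster_alpha: float = 0.05
    fdr_q: float = 0.05
    family_alpha: float = 0.05
    connectivity: str = "faces"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.design, dict):
            self.design = DesignConfig(**self.design)
        if isinstance(self.signal, dict):
            self.signal = SignalParams(**self.signal)
        self.dims = tuple(int(d) for d in self.dims)
        if self.cluster_method not in ("permutation", "mc"):
            raise ValueError("cluster_method must be 'permutation' or 'mc'")
        for name in ("n_perm", "mc_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("voxel_p", "cluster_alpha", "fdr_q", "family_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.data_mode not in ("tmap", "bold"):
            raise ValueError("data_mode must be 'tmap' or 'bold'")

    # seeds for the individual stages, all derived from the master seed
    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def vowel_tasks(self) -> list[str]:
        return [t for t in self.design.tasks if t in VOWEL_TASKS]


# ---------------------------------------------------------------------------
# artifact helpers

def _task_sub(task: str, subject: int) -> str:
    return f"{task}_sub{subject:02d}"


def _load_atlas(out: Path, cfg: PipelineConfig) -> PatternAtlas:
    grid, mask = read_volume(out / "mask.nii")
    regions = {}
    for task in cfg.design.tasks:
        p = out / f"region_{task}.nii"
        if p.exists():
            regions[task] = read_volume(p)[1] > 0.5
    shared = frozenset()
    if cfg.share_tone_with in regions and TONE_TASK in regions:
        if np.any(regions[TONE_TASK] & regions[cfg.share_tone_with]):
            shared = frozenset({TONE_TASK, cfg.share_tone_with})
    return PatternAtlas(grid=grid, mask=mask > 0.5, regions=regions,
                        shared_tasks=shared)


def _load_tmaps(out: Path, cfg: PipelineConfig):
    atlas = _load_atlas(out, cfg)
    trials = read_trial_table(out / "trials.tsv")
    idx = atlas.mask_indices
    tmaps = {}
    for subject in sorted(trials["subject"].unique()):
        for task in cfg.design.tasks:
            p = out / "tmaps" / (_task_sub(task, subject) + ".nii")
            if not p.exists():
                continue
            grid, data4d = read_series(p)
            sub = trials[(trials["subject"] == subject)
                         & (trials["task"] == task)].reset_index(drop=True)
            flat = data4d.reshape(-1, data4d.shape[3], order="F")[idx].T
            tmaps[(subject, task)] = TMapStack(grid=grid, indices=idx,
                                               data=flat, trials=sub)
    return atlas, trials, tmaps


def _save_tmaps(out: Path, tmaps: dict) -> None:
    d = out / "tmaps"
    d.mkdir(exist_ok=True)
    for (subject, task), tm in tmaps.items():
        n_trials = tm.data.shape[0]
        flat = np.zeros((tm.grid.n_voxels, n_trials), dtype=np.float32)
        flat[tm.indices] = tm.data.T
        vol4 = flat.reshape(tm.grid.dims + (n_trials,), order="F")
        write_series(tm.grid, vol4, d / (_task_sub(task, subject) + ".nii"))


def _accuracy_path(out: Path, task: str, subject: int) -> Path:
    return out / "accuracy" / (_task_sub(task, subject) + ".nii")


def _load_accuracy_maps(out: Path, cfg: PipelineConfig, atlas: PatternAtlas):
    idx = atlas.mask_indices
    maps = {}
    for task in cfg.design.tasks:
        maps[task] = []
        for subject in range(1, cfg.design.n_subjects + 1):
            p = _accuracy_path(out, task, subject)
            grid, vol = read_volume(p)
            vals = vol.ravel(order="F")[idx]
            maps[task].append(MaskedVector(grid, idx, vals))
    return maps


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, out: Path):
    """Generate the synthetic dataset (trial table, atlas, per-trial maps)."""
    out.mkdir(parents=True, exist_ok=True)
    design = dataclasses.replace(cfg.design, seed=cfg.stage_seed("design"))
    design.check_tr_locked()
    trials = make_design(design)
    write_trial_table(trials, out / "trials.tsv")
    atlas = make_pattern_atlas(cfg.dims, cfg.voxel_mm, cfg.design.tasks,
                               cfg.region_size_vox, seed=cfg.stage_seed("atlas"),
                               share_tone_with=cfg.share_tone_with,
                               margin_vox=cfg.region_margin_vox)
    write_volume(atlas.grid, atlas.mask.astype(float), out / "mask.nii")
    for task, reg in atlas.regions.items():
        write_volume(atlas.grid, reg.astype(float), out / f"region_{task}.nii")
    signal = dataclasses.replace(cfg.signal, seed=cfg.stage_seed("signal"))
    if cfg.data_mode == "bold":
        tmaps = {}
        for task in cfg.design.tasks:
            # the response window cannot exceed the inter-event spacing, so
            # the HRF and FIR tents are truncated to the trial duration
            spacing_tr = int(round(cfg.design.trial_duration_s(task)
                                   / cfg.design.tr_s))
            hrf = DEFAULT_HRF[:spacing_tr]
            runs = simulate_bold(trials[trials["task"] == task], atlas,
                                 signal, hrf=hrf, tr_s=cfg.design.tr_s)
            n_tents = min(spacing_tr, 5)
            for key, run in runs.items():
                est = FIRTrialEstimator(n_tents=n_tents)
                est.fit(run.data, run.onsets_tr, tr_s=run.tr_s)
                tmaps[key] = TMapStack(grid=run.grid, indices=run.indices,
                                       data=est.trial_patterns_,
                                       trials=run.trials)
    else:
        tmaps = simulate_tmaps(trials, atlas, signal)
    _save_tmaps(out, tmaps)
    log.info("simulate: %d trials, %d tasks, mask %d voxels", len(trials),
             len(cfg.design.tasks), int(atlas.mask.sum()))
    return atlas, trials, tmaps


def stage_searchlight(cfg: PipelineConfig, out: Path, tmaps=None,
                      atlas: PatternAtlas | None = None):
    """Subject-level searchlight accuracy maps for every task."""
    if tmaps is None or atlas is None:
        atlas, _, tmaps = _load_tmaps(out, cfg)
    (out / "accuracy").mkdir(exist_ok=True)
    idx = atlas.mask_indices
    sl = SearchlightRankAccuracy(atlas.grid, idx, cfg.radius_mm,
                                 cfg.min_sphere_frac, cfg.fold_strategy)
    maps = {task: [] for task in cfg.design.tasks}
    for (subject, task), tm in sorted(tmaps.items()):
        sl.fit(tm.data, tm.labels, trials=tm.trials)
        mv = sl.accuracy_map_
        maps[task].append(mv)
        write_volume(atlas.grid, unflatten(mv, fill=np.nan),
                     _accuracy_path(out, task, subject))
    write_volume(atlas.grid,
                 unflatten(MaskedVector(atlas.grid, idx,
                                        sl.skipped_.astype(float))),
                 out / "skipped_centres.nii")
    log.info("searchlight: %d subject maps", sum(len(v) for v in maps.values()))
    return maps


def stage_infer(cfg: PipelineConfig, out: Path, tmaps=None, atlas=None,
                subject_maps=None):
    """Group maps, permutation nulls, p maps, cluster correction, tables."""
    if tmaps is None or atlas is None:
        atlas, _, tmaps = _load_tmaps(out, cfg)
    if subject_maps is None:
        subject_maps = _load_accuracy_maps(out, cfg, atlas)
    idx = atlas.mask_indices
    nulls, cluster_tables, cluster_labels = {}, {}, {}
    fwhm_info, thresholds = {}, {}
    for task in cfg.design.tasks:
        by_subject = {s: tm for (s, t), tm in tmaps.items() if t == task}
        group = inf.group_average(subject_maps[task])
        write_volume(atlas.grid, unflatten(group, fill=np.nan),
                     out / f"group_{task}.nii")
        null = inf.permutation_null(
            by_subject, n_perm=cfg.n_perm,
            seed=cfg.stage_seed(f"null_{task}"), radius_mm=cfg.radius_mm,
            min_sphere_frac=cfg.min_sphere_frac,
            fold_strategy=cfg.fold_strategy)
        nulls[task] = null
        np.save(out / f"null_{task}.npy", null.maps)
        pmap = inf.voxelwise_p(group, null)
        write_volume(atlas.grid, unflatten(pmap, fill=np.nan),
                     out / f"p_{task}.nii")
        # smoothness from (a subsample of) the null maps
        n_fwhm = min(20, null.n_perm)
        null_vols = np.stack([unflatten(MaskedVector(atlas.grid, idx, m),
                                        fill=np.nan)
                              for m in null.maps[:n_fwhm]])
        fwhm = inf.estimate_fwhm(null_vols, atlas.mask, atlas.grid.voxel_mm)
        fwhm_info[task] = [float(f) for f in fwhm]
        if cfg.cluster_method == "permutation":
            thr = inf.cluster_threshold_perm(
                null, cfg.voxel_p, cfg.cluster_alpha,
                connectivity=cfg.connectivity)
        else:
            thr = inf.cluster_threshold_mc(
                atlas.mask, fwhm, atlas.grid.voxel_mm, cfg.voxel_p,
                cfg.cluster_alpha, cfg.mc_iterations,
                seed=cfg.stage_seed(f"mc_{task}"), connectivity=cfg.connectivity)
        thresholds[task] = int(thr)
        keep = pmap.values < cfg.voxel_p
        table, labvol = inf.extract_clusters(group, keep, cfg.connectivity,
                                             min_size=thr)
        cluster_tables[task] = table
        cluster_labels[task] = labvol
        table.to_csv(out / f"clusters_{task}.tsv", sep="\t", index=False)
        write_volume(atlas.grid, labvol.astype(float),
                     out / f"clusterlab_{task}.nii")
        # univariate task engagement: subject-mean trial values vs zero, FDR
        sub_means = np.stack([tm.data.mean(axis=0)
                              for _, tm in sorted(by_subject.items())])
        tvals, pvals = ttest_vs_zero(sub_means)
        finite = np.isfinite(pvals)
        rej = np.zeros(pvals.shape, dtype=bool)
        if finite.any():
            rej[finite] = fdr_bh(pvals[finite], cfg.fdr_q)
        write_volume(atlas.grid,
                     unflatten(MaskedVector(atlas.grid, idx,
                                            rej.astype(float))),
                     out / f"univariate_fdr_{task}.nii")
        log.info("infer[%s]: fwhm=%s, cluster threshold=%d, %d clusters",
                 task, np.round(fwhm, 2).tolist(), thr, len(table))
    with open(out / "inference.json", "w") as fh:
        json.dump({"fwhm_mm": fwhm_info, "cluster_size_threshold": thresholds,
                   "cluster_method": cfg.cluster_method,
                   "n_perm": cfg.n_perm, "mc_iterations": cfg.mc_iterations},
                  fh, indent=2, sort_keys=True)
    return nulls, cluster_tables, cluster_labels


def stage_crosstask(cfg: PipelineConfig, out: Path, atlas=None,
                    subject_maps=None, nulls=None, cluster_labels=None):
    """Cross-task transfer matrices and the spatial-overlap report."""
    if atlas is None:
        atlas = _load_atlas(out, cfg)
    if subject_maps is None:
        subject_maps = _load_accuracy_maps(out, cfg, atlas)
    if nulls is None:
        nulls = {}
        for task in cfg.design.tasks:
            maps = np.load(out / f"null_{task}.npy")
            nulls[task] = inf.NullDistribution(grid=atlas.grid,
                                               indices=atlas.mask_indices,
                                               maps=maps)
    if cluster_labels is None:
        cluster_labels = {
            task: read_volume(out / f"clusterlab_{task}.nii")[1].astype(int)
            for task in cfg.design.tasks}
    vowel_tasks = cfg.vowel_tasks
    cluster_masks = {}
    for task in vowel_tasks:
        lab = cluster_labels[task]
        cluster_masks[task] = [(int(l), lab == l)
                               for l in np.unique(lab) if l > 0]
    vowel_matrix = ct.cross_task_matrix(
        {t: subject_maps[t] for t in vowel_tasks}, cluster_masks,
        {t: nulls[t] for t in vowel_tasks}, probe_tasks=vowel_tasks,
        alpha=cfg.family_alpha)
    vowel_matrix.to_csv(out / "crosstask_vowel.tsv", sep="\t", index=False)
    tone_matrix = pd.DataFrame()
    if TONE_TASK in cfg.design.tasks:
        tone_matrix = ct.cross_task_matrix(
            subject_maps, cluster_masks, nulls, probe_tasks=[TONE_TASK],
            alpha=cfg.family_alpha)
        tone_matrix.to_csv(out / "crosstask_tone.tsv", sep="\t", index=False)
    overlap = ct.spatial_overlap({t: cluster_labels[t] > 0
                                  for t in cfg.design.tasks})
    overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
    log.info("crosstask: %d vowel cells, %d tone cells", len(vowel_matrix),
             len(tone_matrix))
    return vowel_matrix, tone_matrix, overlap


def _format_matrix(df: pd.DataFrame) -> str:
    if df.empty:
        return "  (no clusters survived)\n"
    lines = []
    for _, r in df.iterrows():
        star = " *" if r["significant"] else ""
        lines.append(
            f"  {r['defining_task']:<11s} cluster {int(r['cluster'])} | "
            f"probe {r['probe_task']:<11s} "
            f"acc {100 * r['mean_accuracy']:.1f} ± {100 * r['se']:.1f}%  "
            f"p={r['p']:.3f}{star}")
    return "\n".join(lines) + "\n"


def make_report(out: Path) -> str:
    """Render the cluster tables and cross-task matrices as plain text."""
    out = Path(out)
    missing = []
    parts = ["searchlight MVPA pipeline report", "=" * 34, ""]
    cluster_files = sorted(out.glob("clusters_*.tsv"))
    if not cluster_files:
        missing.append("clusters_*.tsv")
    for p in cluster_files:
        task = p.stem.replace("clusters_", "")
        table = pd.read_csv(p, sep="\t")
        parts.append(f"[{task}] significant clusters: {len(table)}")
        if len(table) == 0:
            parts.append("  no clusters survived correction")
        for _, r in table.iterrows():
            parts.append(
                f"  cluster {int(r['label'])}: {int(r['n_voxels'])} voxels, "
                f"centre of mass ({r['cm_x_mm']:.1f}, {r['cm_y_mm']:.1f}, "
                f"{r['cm_z_mm']:.1f}) mm, peak accuracy {r['peak']:.3f}")
        parts.append("")
    for name, title in [("crosstask_vowel.tsv", "cross-task transfer (vowel tasks)"),
                        ("crosstask_tone.tsv", "tone transfer into vowel clusters")]:
        p = out / name
        if p.exists():
            df = pd.read_csv(p, sep="\t")
            parts.append(title)
            parts.append(_format_matrix(df))
        else:
            missing.append(name)
    p = out / "overlap.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t")
        parts.append("spatial overlap of task cluster masks (voxels)")
        for _, r in df.iterrows():
            parts.append(f"  {r['intersection']}: {int(r['n_voxels'])}")
    else:
        missing.append("overlap.tsv")
    if missing:
        parts.append("")
        parts.append("missing artifacts: " + ", ".join(missing))
    text = "\n".join(parts) + "\n"
    (out / "report.txt").write_text(text)
    return text


def _manifest(out: Path, cfg: PipelineConfig) -> dict:
    entries = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json" and p.suffix != ".log":
            entries[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    return {"seed": cfg.seed, "artifacts": entries}


def run_pipeline(cfg: PipelineConfig, out) -> Path:
    """Run every stage and write the manifest; returns the results directory."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        cfg.to_yaml(out / "config.yaml")
        atlas, trials, tmaps = stage_simulate(cfg, out)
        subject_maps = stage_searchlight(cfg, out, tmaps, atlas)
        nulls, tables, labels = stage_infer(cfg, out, tmaps, atlas, subject_maps)
        stage_crosstask(cfg, out, atlas, subject_maps, nulls, labels)
        make_report(out)
        manifest = _manifest(out, cfg)
        manifest["elapsed_s"] = round(time.time() - t0, 2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        log.exception("pipeline stage failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
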