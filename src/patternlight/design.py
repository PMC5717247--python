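"""Experimental design: trial scheduling for the four auditory tasks.

The emulated slow event-related design has four tasks — tone perception,
vowel listening, vowel imagery and vowel production.  Vowel tasks present
7 vowel classes x 3 recorded exemplars x 2 repetitions = 42 trials; the tone
task presents 7 pure tones, each repeated 6 times, so every sound is equally
represented.  Perceptual trials last 2 s stimulus + 8 s rest; imagery and
production trials add an 8 s maintenance period and a 2 s execution window
(2 + 8 + 2 + 8 = 20 s).  All durations are integer multiples of the 2.5 s TR
so that event onsets are TR-locked.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["DesignConfig", "make_design", "read_trial_table", "write_trial_table",
           "VOWEL_TASKS", "TONE_TASK"]

TONE_TASK = "tone"
VOWEL_TASKS = ("listening", "imagery", "production")
#: tasks whose trials include the maintenance + execution periods
_EXECUTION_TASKS = frozenset({"imagery", "production"})

TRIAL_COLUMNS = ["subject", "task", "class_label", "exemplar", "repetition",
                 "onset_s", "event_onset_s"]


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the emulated experiment (defaults mirror the study design)."""

    n_subjects: int = 15
    tasks: tuple[str, ...] = (TONE_TASK,) + VOWEL_TASKS
    n_classes: int = 7
    n_exemplars: int = 3
    n_repetitions: int = 2
    stim_s: float = 2.0
    maintenance_s: float = 8.0
    execution_s: float = 2.0
    rest_s: float = 8.0
    tr_s: float = 2.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_classes", "n_exemplars", "n_repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("stim_s", "maintenance_s", "execution_s", "rest_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        object.__setattr__(self, "tasks", tuple(self.tasks))

    def trial_duration_s(self, task: str) -> float:
        if task in _EXECUTION_TASKS:
            return self.stim_s + self.maintenance_s + self.execution_s + self.rest_s
        return self.stim_s + self.rest_s

    def event_delay_s(self, task: str) -> float:
        """Delay from trial onset to the event whose response is decoded."""
        if task in _EXECUTION_TASKS:
            return self.stim_s + self.maintenance_s
        return 0.0

    def trials_per_task(self, task: str) -> int:
        return self.n_classes * self.n_exemplars * self.n_repetitions

    def check_tr_locked(self) -> None:
        """Require every trial duration and event delay to sit on the TR grid."""
        for task in self.tasks:
            for value in (self.trial_duration_s(task), self.event_delay_s(task)):
                if abs(value / self.tr_s - round(value / self.tr_s)) > 1e-9:
                    raise ValueError(
                        f"duration {value}s of task {task!r} is not a multiple "
                        f"of TR {self.tr_s}s"
                    )

    def to_dict(self) -> dict:
        return asdict(self)


def _task_triples(config: DesignConfig, task: str) -> list[tuple[int, int, int]]:
    """(class, exemplar, repetition) triples for one task."""
    if task == TONE_TASK:
        # tones have a single exemplar; repetitions chosen so that the trial
        # count matches the vowel tasks (every sound equally represented)
        n_rep = config.n_exemplars * config.n_repetitions
        return [(c, 1, r)
                for c in range(1, config.n_classes + 1)
                for r in range(1, n_rep + 1)]
    return [(c, e, r)
            for c in range(1, config.n_classes + 1)
            for e in range(1, config.n_exemplars + 1)
            for r in range(1, config.n_repetitions + 1)]


def make_design(config: DesignConfig) -> pd.DataFrame:
    """Build the randomized trial table for all subjects and tasks.

    Each (subject, task) gets one run; trial order is shuffled per run with a
    generator derived from ``config.seed``, so the schedule is reproducible.
    Columns: subject, task, class_label, exemplar, repetition, onset_s,
    event_onset_s (the onset of the decoded event: stimulus for perceptual
    tasks, execution for imagery/production).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rows = []
    for subject in range(1, config.n_subjects + 1):
        for task in config.tasks:
            triples = _task_triples(config, task)
            order = rng.permutation(len(triples))
            dur = config.trial_duration_s(task)
            delay = config.event_delay_s(task)
            for pos, j in enumerate(order):
                c, e, r = triples[j]
                onset = pos * dur
                rows.append((subject, task, c, e, r, onset, onset + delay))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    _validate_trial_table(df, config)
    return df


def _validate_trial_table(df: pd.DataFrame, config: DesignConfig) -> None:
    for (subject, task), sub in df.groupby(["subject", "task"], sort=False):
        if task in VOWEL_TASKS and task in config.tasks:
            expected = config.n_classes * config.n_exemplars * config.n_repetitions
            if len(sub) != expected:
                raise AssertionError(
                    f"subject {subject} task {task}: {len(sub)} trials, "
                    f"expected {expected}"
                )
            triples = sub[["class_label", "exemplar", "repetition"]]
            if triples.duplicated().any():
                raise AssertionError("duplicate (class, exemplar, repetition) triple")
        if np.any(np.diff(sub["onset_s"].to_numpy()) <= 0):
            raise AssertionError("onsets must be strictly increasing within a run")


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
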