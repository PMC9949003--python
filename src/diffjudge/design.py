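"""Experiment designs, coherence bookkeeping and trial-table I/O.

A *condition* is one stimulus configuration: the signed coherence of each
random-dot patch (one patch for the color task), plus a stimulus duration
for controlled-duration tasks. Trial tables are plain pandas DataFrames
with one row per trial and a documented CSV representation.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import STRENGTH_LEVELS, signed_levels

#: Stimulus durations of the controlled-duration task (s).
DURATIONS = (0.1, 0.15, 0.25, 0.45, 0.85, 1.65)

TASKS = (
    "color_rt",
    "difficulty_rt_unknown",
    "difficulty_rt_known",
    "difficulty_cd_unknown",
    "difficulty_cd_known",
)

#: Columns of the trial CSV. Missing fields are written as empty strings.
TRIAL_COLUMNS = ["subject", "task", "c1_signed", "c2_signed", "duration",
                 "choice", "rt", "correct"]

_MAX_RT = 5.0  # "too slow" deadline (s)
_MIN_RT = 0.2  # "too early" window (s)


@dataclass(frozen=True)
class Condition:
    """One stimulus condition.

    ``c1_signed``/``c2_signed`` are signed color coherences (2*(pblue-0.5));
    ``c2_signed`` is None for the single-patch color task. ``duration`` is
    the stimulus duration in seconds (None for reaction-time tasks).
    """

    task: str
    c1_signed: float
    c2_signed: Optional[float] = None
    duration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        for c in (self.c1_signed, self.c2_signed):
            if c is not None and abs(c) > 0.64 + 1e-12:
                raise ValueError(f"|coherence| must be <= 0.64, got {c}")
        if self.task.endswith("_known") and self.c2_signed is not None:
            if np.sign(self.c1_signed) * np.sign(self.c2_signed) < 0:
                raise ValueError("known-color conditions must share a sign")


def signed_coherence(pblue: float) -> float:
    """Signed color coherence from the per-dot probability of blue.

    Defined as ``2 * (pblue - 0.5)``: zero for a neutral stimulus, positive
    for blue-dominant stimuli, and +/-0.64 at the extreme pblue of 0.82/0.18.
    """
    p = np.asarray(pblue, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("pblue must lie in [0, 1]")
    out = 2.0 * (p - 0.5)
    return float(out) if np.isscalar(pblue) else out


def _repeat(conds: list[Condition], reps: int,
            equal_strength_frequency: float) -> list[Condition]:
    out: list[Condition] = []
    for cond in conds:
        r = reps
        if cond.c2_signed is not None and abs(abs(cond.c1_signed) - abs(cond.c2_signed)) < 1e-12:
            r = max(1, int(round(reps * equal_strength_frequency)))
        out.extend([cond] * r)
    return out


def make_design(task: str, reps: int = 1,
                equal_strength_frequency: float = 1.0) -> list[Condition]:
    """Enumerate the conditions of a task.

    ``difficulty_rt_unknown`` crosses all 12 x 12 signed-coherence pairs;
    known-color tasks use the 6 x 6 same-sign pairs per color block (both
    blocks returned); controlled-duration tasks cross each pair with the 6
    stimulus durations. Equal-strength pairs (|c1| == |c2|) are repeated
    ``round(reps * equal_strength_frequency)`` times instead of ``reps``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sl = signed_levels()
    if task == "color_rt":
        base = [Condition(task, c) for c in sl]
        return _repeat(base, reps, equal_strength_frequency)
    if task == "difficulty_rt_unknown":
        base = [Condition(task, c1, c2) for c1, c2 in itertools.product(sl, sl)]
        return _repeat(base, reps, equal_strength_frequency)
    if task == "difficulty_rt_known":
        base = []
        for sign in (+1.0, -1.0):
            lv = [sign * c for c in STRENGTH_LEVELS]
            base += [Condition(task, c1, c2) for c1, c2 in itertools.product(lv, lv)]
        return _repeat(base, reps, equal_strength_frequency)
    if task == "difficulty_cd_unknown":
        base = [Condition(task, c1, c2, duration=dur)
                for (c1, c2), dur in itertools.product(
                    itertools.product(sl, sl), DURATIONS)]
        return _repeat(base, reps, equal_strength_frequency)
    # difficulty_cd_known
    base = []
    for sign in (+1.0, -1.0):
        lv = [sign * c for c in STRENGTH_LEVELS]
        base += [Condition(task, c1, c2, duration=dur)
                 for (c1, c2), dur in itertools.product(
                     itertools.product(lv, lv), DURATIONS)]
    return _repeat(base, reps, equal_strength_frequency)


def shuffle_design(conditions: Sequence[Condition], seed: int) -> list[Condition]:
    """Seeded random presentation order."""
    rng = np.random.default_rng(seed)
    conds = list(conditions)
    order = rng.permutation(len(conds))
    return [conds[i] for i in order]


def conditions_to_frame(conditions: Sequence[Condition]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "task": [c.task for c in conditions],
            "c1_signed": [c.c1_signed for c in conditions],
            "c2_signed": [np.nan if c.c2_signed is None else c.c2_signed
                          for c in conditions],
            "duration": [np.nan if c.duration is None else c.duration
                         for c in conditions],
        }
    )


def _valid_coherences() -> np.ndarray:
    return np.asarray(sorted({s * c for c in STRENGTH_LEVELS for s in (-1, 1)}
                             | set()), dtype=float)


def validate_trials(trials: pd.DataFrame, strict_rt: bool = True) -> None:
    """Raise ValueError (with the offending row index) on invalid rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    levels = np.asarray(signed_levels())
    for col in ("c1_signed", "c2_signed"):
        vals = trials[col].to_numpy(dtype=float)
        ok = np.isnan(vals) | (np.abs(vals[:, None] - levels[None, :]) < 1e-9).any(axis=1)
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            raise ValueError(f"row {i}: {col}={vals[i]} not a valid coherence level")
    rt = trials["rt"].to_numpy(dtype=float)
    is_rt_task = trials["task"].astype(str).str.contains("_rt").to_numpy()
    if strict_rt:
        bad = is_rt_task & ~np.isnan(rt) & ((rt <= _MIN_RT) | (rt > _MAX_RT))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"row {i}: rt={rt[i]} outside ({_MIN_RT}, {_MAX_RT}] s")
    ch = trials["choice"].to_numpy()
    ok = np.isin(ch, (1, 2))
    if not ok.all():
        i = int(np.flatnonzero(~ok)[0])
        raise ValueError(f"row {i}: choice={ch[i]} must be 1 (S1/blue) or 2 (S2/yellow)")


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV (UTF-8, '.' decimal, empty for missing)."""
    trials.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path, strict_rt: bool = True) -> pd.DataFrame:
    """Read and validate a trial CSV written by :func:`write_trials`."""
    trials = pd.read_csv(path)
    validate_trials(trials, strict_rt=strict_rt)
    return trials[TRIAL_COLUMNS]
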