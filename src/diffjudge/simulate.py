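"""Monte-Carlo simulators for the difficulty-judgment models.

Five reaction-time models share one accumulation scheme (serial,
time-multiplexed sampling of the two patches) and one collapsing bound
``B(t) = u / (1 + exp(a (t - d)))`` applied to a model-specific decision
quantity:

- ``race``            — each DV races to +/-B; first crossing wins.
- ``difference``      — |DV_S1| - |DV_S2| against +/-B.
- ``two_step``        — a mini color decision at bound ``b_mini`` fixes the
                        sign of each DV, then the sign-weighted difference
                        is bounded.
- ``abs_momentary``   — per-step increments enter as absolute values; the
                        DV difference is bounded.
- ``difference_known``— sign-corrected DV difference when the dominant
                        color is known.

These simulators double as the package's synthetic-data generator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import (RACE, DIFFERENCE, TWO_STEP, ABS_MOMENTARY, DIFF_KNOWN,
                       CONF_UNKNOWN, CONF_KNOWN)
from .design import Condition, TRIAL_COLUMNS
from .params import DifficultyParams, SIGMA_TND, signed_levels

MODEL_IDS = {
    "race": RACE,
    "difference": DIFFERENCE,
    "two_step": TWO_STEP,
    "abs_momentary": ABS_MOMENTARY,
    "difference_known": DIFF_KNOWN,
    "confidence": CONF_UNKNOWN,
    "confidence_known": CONF_KNOWN,
}

#: Models fit with 5 free parameters; the Two-step model adds b_mini.
N_FREE_PARAMS = {"race": 5, "difference": 5, "two_step": 6, "abs_momentary": 5,
                 "difference_known": 5, "confidence": 5, "confidence_known": 5}

DEFAULT_DT = 0.005
DEFAULT_HORIZON = 10.0


@dataclass
class AccumulatorState:
    """Serial accumulator state: two DVs and elapsed decision time."""

    dv_s1: float = 0.0
    dv_s2: float = 0.0
    t: float = 0.0


def step_serial(state: AccumulatorState, c1_signed: float, c2_signed: float,
                kappa: float, dt: float, rng: np.random.Generator) -> AccumulatorState:
    """Advance the serial accumulator by one step.

    Stimulus S1 receives the increment on even steps, S2 on odd steps, so
    each stimulus is sampled for half of the elapsed time.
    """
    k = int(round(state.t / dt))
    inc = rng.normal(0.0, np.sqrt(dt))
    if k % 2 == 0:
        return AccumulatorState(state.dv_s1 + kappa * c1_signed * dt + inc,
                                state.dv_s2, state.t + dt)
    return AccumulatorState(state.dv_s1,
                            state.dv_s2 + kappa * c2_signed * dt + inc,
                            state.t + dt)


def serial_paths(c1_signed: float, c2_signed: float, kappa: float, dt: float,
                 n_steps: int, n_paths: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized unbounded serial accumulation (for diagnostics/tests)."""
    inc = rng.normal(0.0, np.sqrt(dt), size=(n_paths, n_steps))
    drift = np.where(np.arange(n_steps) % 2 == 0,
                     kappa * c1_signed * dt, kappa * c2_signed * dt)
    inc += drift
    dv1 = inc[:, 0::2].sum(axis=1)
    dv2 = inc[:, 1::2].sum(axis=1)
    return dv1, dv2


def _known_sign(c1: float, c2: Optional[float]) -> float:
    s1 = -1.0 if np.signbit(c1) else 1.0
    if c2 is not None:
        s2 = -1.0 if np.signbit(c2) else 1.0
        if s1 != s2 and abs(c1) > 0 and abs(c2) > 0:
            raise ValueError("known-color simulation requires same-sign coherences")
        if abs(c1) == 0 and abs(c2) > 0:
            return s2
    return s1


def _condition_arrays(conditions: Sequence[Condition], known: bool):
    c1 = np.array([c.c1_signed for c in conditions], dtype=float)
    c2 = np.array([0.0 if c.c2_signed is None else c.c2_signed for c in conditions],
                  dtype=float)
    if known:
        ks = np.array([_known_sign(c.c1_signed, c.c2_signed) for c in conditions])
    else:
        ks = np.ones(len(conditions))
    return c1, c2, ks


def _label_correct(choice: np.ndarray, c1: np.ndarray, c2: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """1 when the chosen stimulus is strictly easier; ties are a seeded coin flip."""
    s1, s2 = np.abs(c1), np.abs(c2)
    easier = np.where(s1 > s2, 1, np.where(s2 > s1, 2, 0))
    tie = easier == 0
    easier = np.where(tie, rng.integers(1, 3, size=choice.shape), easier)
    return (choice == easier).astype(int)


def simulate_model(model: str, params: DifficultyParams,
                   conditions: Sequence[Condition], n: int, seed: int,
                   dt: float = DEFAULT_DT, horizon: float = DEFAULT_HORIZON,
                   subject: int = 0) -> pd.DataFrame:
    """Simulate ``n`` trials per condition under a named difficulty model.

    Returns a trial table (one row per trial, condition-major) with the
    decision time plus a truncated-Gaussian non-decision time in ``rt``.
    Paths not absorbed by ``horizon`` are flagged in the ``censored`` column
    and carry the sign of the decision quantity at the horizon.
    """
    if model not in MODEL_IDS:
        raise ValueError(f"unknown model {model!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    model_id = MODEL_IDS[model]
    known = model in ("difference_known", "confidence_known")
    if model_id == TWO_STEP and params.b_mini is None:
        raise ValueError("two_step model requires b_mini")
    c1, c2, ks = _condition_arrays(conditions, known)
    levels = np.asarray(signed_levels())
    b_mini = params.b_mini if params.b_mini is not None else 0.0
    choice, td, censored = _kernels.simulate_rt_models(
        model_id, c1, c2, ks, n, params.kappa, params.u, params.a, params.d,
        b_mini, dt, horizon, levels, int(seed) % (2 ** 31 - 1),
        np.empty(0))  # fresh per-step draws for data generation
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    tnd = np.maximum(rng.normal(params.tnd, SIGMA_TND, size=td.shape), 1e-6)
    c1_full = np.repeat(c1, n)
    c2_full = np.repeat(c2, n)
    out = pd.DataFrame({
        "subject": subject,
        "task": conditions[0].task,
        "c1_signed": c1_full,
        "c2_signed": c2_full,
        "duration": np.nan,
        "choice": choice.astype(int),
        "rt": td + tnd,
        "correct": _label_correct(choice, c1_full, c2_full, rng),
    })[TRIAL_COLUMNS]
    out["censored"] = censored
    return out


def simulate_race(params, conditions, n, seed, **kw) -> pd.DataFrame:
    return simulate_model("race", params, conditions, n, seed, **kw)


def simulate_difference(params, conditions, n, seed, **kw) -> pd.DataFrame:
    return simulate_model("difference", params, conditions, n, seed, **kw)


def simulate_two_step(params, conditions, n, seed, **kw) -> pd.DataFrame:
    return simulate_model("two_step", params, conditions, n, seed, **kw)


def simulate_abs_momentary(params, conditions, n, seed, **kw) -> pd.DataFrame:
    return simulate_model("abs_momentary", params, conditions, n, seed, **kw)


def simulate_difference_known(params, conditions, n, seed, **kw) -> pd.DataFrame:
    return simulate_model("difference_known", params, conditions, n, seed, **kw)


def mean_rt_by_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per (c1_signed, c2_signed) cell."""
    return (trials.groupby(["c1_signed", "c2_signed"], as_index=False)["rt"]
            .mean())
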