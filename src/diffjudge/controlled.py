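"""Controlled-duration difficulty task: buffer model and choice fits.

Stimuli are shown for an experimenter-controlled duration; a sensory
buffer of 80 ms lets both evidence streams in before accumulation becomes
serial, so each stimulus is effectively sampled for
``t_buf + (t_stim - t_buf)/2`` (or the full duration for very short
stimuli). Choices arise from a collapsing-bound crossing during the
stimulus, or from the sign of the decision quantity at stimulus offset.
Fitting is by exact binomial likelihood of per-cell choice counts against
simulated choice probabilities.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from . import _kernels
from .design import Condition, TRIAL_COLUMNS
from .params import DifficultyParams
from .simulate import _condition_arrays, _label_correct, DEFAULT_DT

#: Sensory buffer duration (s).
T_BUF = 0.08

_P_FLOOR = 1e-6


def effective_duration(t_stim, t_buf: float = T_BUF):
    """Per-stimulus sampling time given the stimulus duration.

    Equals ``t_stim`` when the whole stimulus fits in the buffer, otherwise
    ``t_buf + (t_stim - t_buf) / 2``: buffered evidence is used in full and
    the remainder is time-shared between the two stimuli. Continuous at
    ``t_stim = t_buf`` with slope 1 then 1/2.
    """
    t = np.asarray(t_stim, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t_stim must be positive")
    out = np.where(t <= t_buf, t, t_buf + (t - t_buf) / 2.0)
    return float(out) if np.isscalar(t_stim) else out


def simulate_cd(params: DifficultyParams, conditions: Sequence[Condition],
                n: int, seed: int, known: bool = False, t_buf: float = T_BUF,
                dt: float = DEFAULT_DT, subject: int = 0,
                noise: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Simulate controlled-duration choices (no RTs).

    ``known`` selects the sign-corrected decision rule; conditions must
    carry durations. The ``correct`` column labels ties by a seeded coin.
    ``noise`` (optional) is a pre-generated N(0,1) pool used for common
    random numbers during fitting; by default draws are fresh.
    """
    durations = np.array([c.duration for c in conditions], dtype=float)
    if np.any(np.isnan(durations)):
        raise ValueError("controlled-duration conditions need durations")
    c1, c2, ks = _condition_arrays(conditions, known)
    known_flags = np.full(len(conditions), known)
    if noise is None:
        noise = np.empty(0)
    choice, crossed = _kernels.simulate_cd_models(
        known_flags, c1, c2, ks, durations, n, params.kappa, params.u,
        params.a, params.d, dt, t_buf, int(seed) % (2 ** 31 - 1), noise)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    c1_full = np.repeat(c1, n)
    c2_full = np.repeat(c2, n)
    out = pd.DataFrame({
        "subject": subject,
        "task": conditions[0].task,
        "c1_signed": c1_full,
        "c2_signed": c2_full,
        "duration": np.repeat(durations, n),
        "choice": choice.astype(int),
        "rt": np.nan,
        "correct": _label_correct(choice, c1_full, c2_full, rng),
    })[TRIAL_COLUMNS]
    out["crossed"] = crossed
    return out


def _cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(c1, c2, duration) choice counts, equal-strength cells excluded."""
    t = trials[np.abs(trials["c1_signed"].abs() - trials["c2_signed"].abs()) > 1e-12]
    t = t[np.sign(t["c1_signed"]) * np.sign(t["c2_signed"]) >= 0]  # same-sign only
    g = t.groupby(["c1_signed", "c2_signed", "duration"])
    out = g["choice"].agg(n="count", k=lambda c: int((c == 1).sum()))
    return out.reset_index()


def cd_loglik(theta: np.ndarray, cells_known: Optional[pd.DataFrame],
              cells_unknown: Optional[pd.DataFrame], shared_kappa: bool,
              t_buf: float, n_sim: int, dt: float, seed: int,
              noise: Optional[np.ndarray] = None) -> float:
    """Binomial log-likelihood of per-cell choice counts.

    ``theta`` is (kappa, u, a, d) with shared kappa, or
    (kappa_unknown, kappa_known, u, a, d) otherwise. Simulated choice
    probabilities use common random numbers (a fixed seed), are computed
    from ``n_sim`` trials per cell, and are floored away from 0/1.
    """
    if shared_kappa:
        kap_u = kap_k = theta[0]
        u, a, d = theta[1:]
    else:
        kap_u, kap_k = theta[0], theta[1]
        u, a, d = theta[2:]
    total = 0.0
    for known, cells, kap in ((False, cells_unknown, kap_u),
                              (True, cells_known, kap_k)):
        if cells is None or len(cells) == 0:
            continue
        task = "difficulty_cd_known" if known else "difficulty_cd_unknown"
        conds = [Condition(task, r.c1_signed, r.c2_signed, duration=r.duration)
                 for r in cells.itertuples()]
        params = DifficultyParams(kappa=kap, u=u, a=a, d=d, tnd=0.3)
        sim = simulate_cd(params, conds, n_sim, seed, known=known,
                          t_buf=t_buf, dt=dt, noise=noise)
        p1 = (sim["choice"].to_numpy() == 1).reshape(len(conds), n_sim).mean(axis=1)
        p1 = np.clip(p1, _P_FLOOR, 1.0 - _P_FLOOR)
        k = cells["k"].to_numpy()
        n = cells["n"].to_numpy()
        total += float((k * np.log(p1) + (n - k) * np.log(1.0 - p1)).sum())
    return total


_CD_BOUNDS = {"kappa": (0.5, 40.0), "u": (0.1, 10.0), "a": (-5.0, 10.0),
              "d": (-2.0, 10.0)}


class ControlledDurationModel(BaseEstimator):
    """Joint known/unknown controlled-duration fit (sklearn estimator style).

    With ``shared_kappa`` the model has 4 free parameters (kappa, u, a, d);
    otherwise the known and unknown conditions get separate drift
    coefficients (5 parameters). Equal-strength and mixed-color trials are
    excluded from the likelihood. Fitted attributes: ``params_`` (dict),
    ``loglik_``, ``bic_``, ``n_trials_``.
    """

    def __init__(self, shared_kappa: bool = True, t_buf: float = T_BUF,
                 n_sim: int = 2000, dt: float = DEFAULT_DT,
                 n_starts: int = 3, max_evals: int = 150,
                 random_state: int = 0):
        self.shared_kappa = shared_kappa
        self.t_buf = t_buf
        self.n_sim = n_sim
        self.dt = dt
        self.n_starts = n_starts
        self.max_evals = max_evals
        self.random_state = random_state

    def fit(self, trials: pd.DataFrame) -> "ControlledDurationModel":
        known = trials[trials["task"] == "difficulty_cd_known"]
        unknown = trials[trials["task"] == "difficulty_cd_unknown"]
        cells_k = _cells(known) if len(known) else None
        cells_u = _cells(unknown) if len(unknown) else None
        if cells_k is None and cells_u is None:
            raise ValueError("no controlled-duration trials to fit")
        sim_seed = int(np.random.default_rng(self.random_state).integers(2 ** 31 - 1))
        noise = np.random.default_rng(sim_seed).standard_normal(1 << 21)

        def neg(theta):
            return -cd_loglik(theta, cells_k, cells_u, self.shared_kappa,
                              self.t_buf, self.n_sim, self.dt, sim_seed, noise)

        names = (["kappa", "u", "a", "d"] if self.shared_kappa
                 else ["kappa", "kappa", "u", "a", "d"])
        bnds = [_CD_BOUNDS[n] for n in names]
        lo = np.array([b[0] for b in bnds])
        hi = np.array([b[1] for b in bnds])
        span = hi - lo
        rng = np.random.default_rng(self.random_state)
        start0 = (np.array([8.0, 1.5, 2.0, 0.5]) if self.shared_kappa
                  else np.array([8.0, 8.0, 1.5, 2.0, 0.5]))
        unit = [(0.0, 1.0)] * len(names)
        neg_unit = lambda z: neg(lo + np.clip(z, 0.0, 1.0) * span)
        best = None
        for s in range(self.n_starts):
            z0 = (start0 - lo) / span if s == 0 else rng.uniform(
                0.1, 0.9, len(names))
            res = optimize.minimize(neg_unit, z0, method="Nelder-Mead",
                                    bounds=unit,
                                    options={"maxfev": self.max_evals,
                                             "adaptive": True,
                                             "xatol": 1e-4, "fatol": 0.01})
            if best is None or res.fun < best.fun:
                best = res
        th = lo + np.clip(best.x, 0.0, 1.0) * span
        if self.shared_kappa:
            self.params_ = {"kappa": th[0], "u": th[1], "a": th[2], "d": th[3]}
        else:
            self.params_ = {"kappa_unknown": th[0], "kappa_known": th[1],
                            "u": th[2], "a": th[3], "d": th[4]}
        self.loglik_ = -float(best.fun)
        n_tr = int((cells_k["n"].sum() if cells_k is not None else 0) +
                   (cells_u["n"].sum() if cells_u is not None else 0))
        self.n_trials_ = n_tr
        self.bic_ = len(th) * np.log(n_tr) - 2.0 * self.loglik_
        return self


def fit_cd(trials_known: pd.DataFrame, trials_unknown: pd.DataFrame,
           shared_kappa: bool = True, t_buf: float = T_BUF,
           **kw) -> ControlledDurationModel:
    """Functional wrapper: concatenates the two tasks and fits jointly."""
    est = ControlledDurationModel(shared_kappa=shared_kappa, t_buf=t_buf, **kw)
    return est.fit(pd.concat([trials_known, trials_unknown], ignore_index=True))


def log10_bayes_factor(bic_a: float, bic_b: float) -> float:
    """log10 Bayes factor favoring model a, from the BIC approximation."""
    return (bic_b - bic_a) / (2.0 * np.log(10.0))
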