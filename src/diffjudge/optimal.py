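"""Reward-rate-optimal policy for the difficulty task.

The task is a POMDP whose belief state is fully summarized by
``(t_S1, t_S2, DV_S1, DV_S2)``: elapsed sampling time and accumulated
evidence per stimulus. Under strict serial alternation (S1 on even sample
counts) the two times are determined by the total sample count, so the
solver works on slices indexed by that count, with the two DVs discretized
on a grid. Actions are: choose S1, choose S2, or sample the next stimulus.
Values are computed by backward induction for a candidate reward rate
``rho``; the optimal rho makes the value of the initial (zero-evidence)
state exactly zero and is found by bisection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import STRENGTH_LEVELS, signed_levels

CHOOSE_S1, CHOOSE_S2, SAMPLE = 0, 1, 2


@dataclass
class MDPConfig:
    """Configuration of the belief-state MDP.

    Defaults follow the printed simulation protocol: kappa=13, Rc=1, Rn=0,
    error time penalty 1 s, mean non-decision time 0.4 s, inter-trial
    interval 0.5 s, dt=0.05 s, dDV=0.1.
    """

    kappa: float = 13.0
    rc: float = 1.0
    rn: float = 0.0
    tp: float = 1.0
    tnd_mean: float = 0.4
    tw: float = 0.5
    dt: float = 0.05
    d_dv: float = 0.1
    dv_max: float = 24.0
    horizon: float = 6.0
    known: bool = False          # known color: prior on positive coherences only
    leak_tol: float = 0.02

    @property
    def levels(self) -> np.ndarray:
        if self.known:
            return np.asarray(STRENGTH_LEVELS, dtype=float)
        return np.asarray(signed_levels(), dtype=float)


@dataclass
class Policy:
    """Optimal actions on the (sample count, DV_S1, DV_S2) grid."""

    actions: np.ndarray   # int8 (n_slices+1, n_dv, n_dv)
    values: np.ndarray    # float (n_dv, n_dv) value at slice 0
    dv_grid: np.ndarray
    rho: float
    config: MDPConfig
    v0: float             # value of the initial state under rho
    max_leak: float = 0.0

    def action(self, k: int, dv1: float, dv2: float) -> int:
        i1 = int(np.clip(round(dv1 / self.config.d_dv) + (len(self.dv_grid) // 2),
                         0, len(self.dv_grid) - 1))
        i2 = int(np.clip(round(dv2 / self.config.d_dv) + (len(self.dv_grid) // 2),
                         0, len(self.dv_grid) - 1))
        return int(self.actions[k, i1, i2])


def posterior_coherence(dv: float, t: float, kappa: float,
                        prior_levels: np.ndarray) -> np.ndarray:
    """Posterior over signed coherences given one stimulus's DV and time.

    Proportional to ``Normal(dv | kappa*c*t, t) * P(c)`` with a uniform
    prior; returns the prior itself at t = 0. Normalized to sum to 1.
    """
    levels = np.asarray(prior_levels, dtype=float)
    if t <= 0:
        return np.full(len(levels), 1.0 / len(levels))
    logw = -0.5 * (dv - kappa * levels * t) ** 2 / t
    w = np.exp(logw - logw.max())
    return w / w.sum()


def omega(a: float, b: float) -> float:
    """Tie-broken indicator that |a| > |b| (0.5 on ties)."""
    if abs(a) > abs(b):
        return 1.0
    if abs(a) < abs(b):
        return 0.0
    return 0.5


def _omega_matrix(levels: np.ndarray) -> np.ndarray:
    av = np.abs(levels)
    return np.where(av[:, None] > av[None, :], 1.0,
                    np.where(av[:, None] < av[None, :], 0.0, 0.5))


def prob_correct_choice(dv1: float, t1: float, dv2: float, t2: float,
                        config: MDPConfig, choice: int = 1) -> float:
    """Probability that choosing stimulus ``choice`` (1 or 2) is correct."""
    lv = config.levels
    p1 = posterior_coherence(dv1, t1, config.kappa, lv)
    p2 = posterior_coherence(dv2, t2, config.kappa, lv)
    b1 = float(p1 @ _omega_matrix(lv) @ p2)
    return b1 if choice == 1 else 1.0 - b1


def _posterior_table(config: MDPConfig, dv_grid: np.ndarray,
                     n_times: int) -> np.ndarray:
    """post[nt, i_dv, c]: posterior after nt samples of one stimulus."""
    lv = config.levels
    post = np.empty((n_times, len(dv_grid), len(lv)))
    post[0] = 1.0 / len(lv)
    for nt in range(1, n_times):
        t = nt * config.dt
        logw = -0.5 * (dv_grid[:, None] - config.kappa * lv[None, :] * t) ** 2 / t
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        post[nt] = w / w.sum(axis=1, keepdims=True)
    return post


def _bin_probs(config: MDPConfig) -> tuple[np.ndarray, int]:
    """Per-coherence probabilities of the DV increment falling in each
    dDV-wide bin (edge bins absorb the Gaussian tails)."""
    lv = config.levels
    half_span = config.kappa * np.abs(lv).max() * config.dt + 5.0 * np.sqrt(config.dt)
    J = int(np.ceil(half_span / config.d_dv))
    offs = np.arange(-J, J + 1) * config.d_dv
    edges = np.concatenate([[-np.inf], offs[:-1] + config.d_dv / 2, [np.inf]])
    mean = config.kappa * lv * config.dt
    sd = np.sqrt(config.dt)
    cdf = norm.cdf((edges[None, :] - mean[:, None]) / sd)
    return np.diff(cdf, axis=1), J


def solve_bellman(config: MDPConfig, rho: float,
                  check_leak: bool = False) -> Policy:
    """Backward induction for a candidate reward rate.

    The choose-value of a state is the expected reward minus the
    opportunity cost of the dead time, ``b*Rc + (1-b)*Rn - (1-b)*tp*rho -
    (tnd + tw)*rho``; sampling costs ``rho*dt`` plus the marginal value of
    the updated belief. Sampling is unavailable at the terminal slice.
    """
    dt, ddv = config.dt, config.d_dv
    nb = int(round(config.dv_max / ddv))
    dv_grid = np.arange(-nb, nb + 1) * ddv
    N = len(dv_grid)
    K = int(round(config.horizon / dt))
    n_times = K // 2 + 2
    post = _posterior_table(config, dv_grid, n_times)
    binp, J = _bin_probs(config)
    omg = _omega_matrix(config.levels)
    # mixture transition kernel per (samples-so-far, current dv, offset bin)
    kern = np.einsum("tic,cj->tij", post, binp)
    tgt_raw = np.arange(N)[:, None] + np.arange(-J, J + 1)[None, :]
    off_grid = (tgt_raw < 0) | (tgt_raw >= N)
    tgt = np.clip(tgt_raw, 0, N - 1)
    # Off-grid transition mass is clamped to the edge bin. When the sampled
    # stimulus's posterior is already saturated at an extreme coherence this
    # is belief-equivalent (the DV level carries no further information), so
    # the leak diagnostic weights clamped mass by posterior non-saturation,
    # and only over states reachable from the origin in the elapsed time.
    unsat = 1.0 - post.max(axis=2)
    cmax = np.abs(config.levels).max()
    t_of = np.arange(n_times) * dt
    reach = (np.abs(dv_grid)[None, :] <=
             config.kappa * cmax * t_of[:, None]
             + 6.0 * np.sqrt(t_of)[:, None] + ddv)
    leak = (np.einsum("tij,ij->ti", kern, off_grid.astype(float))
            * unsat * reach)

    dead_cost = (config.tnd_mean + config.tw) * rho
    actions = np.empty((K + 1, N, N), dtype=np.int8)
    n1 = lambda k: (k + 1) // 2
    n2 = lambda k: k // 2

    def choose_values(k):
        b = post[n1(k)] @ omg @ post[n2(k)].T   # P(choose S1 correct)
        v1 = b * config.rc + (1 - b) * config.rn - (1 - b) * config.tp * rho - dead_cost
        b2 = 1.0 - b
        v2 = b2 * config.rc + (1 - b2) * config.rn - (1 - b2) * config.tp * rho - dead_cost
        return v1, v2

    v1, v2 = choose_values(K)
    V_next = np.maximum(v1, v2)
    actions[K] = np.where(v1 >= v2, CHOOSE_S1, CHOOSE_S2)
    max_leak = 0.0
    V0_grid = V_next
    for k in range(K - 1, -1, -1):
        v1, v2 = choose_values(k)
        if k % 2 == 0:   # S1 is sampled next; its time-in-samples so far is n1(k)
            Kc = kern[n1(k)]
            G = V_next[tgt, :]                  # (N, 2J+1, N)
            SV = np.einsum("ij,ijk->ik", Kc, G) - rho * dt
            lk = leak[n1(k)][:, None]
        else:
            Kc = kern[n2(k)]
            G = V_next[:, tgt]                  # (N, N, 2J+1)
            SV = np.einsum("kj,ikj->ik", Kc, G) - rho * dt
            lk = leak[n2(k)][None, :]
        stacked = np.stack([v1, v2, SV])
        act = stacked.argmax(axis=0)
        V_next = stacked.max(axis=0)
        actions[k] = act
        if check_leak:
            m = float(np.max(np.where(act == SAMPLE, lk * np.ones_like(SV), 0.0)))
            max_leak = max(max_leak, m)
        V0_grid = V_next
    if check_leak and max_leak > config.leak_tol:
        raise RuntimeError(
            f"transition mass {max_leak:.3g} leaves the DV grid from states "
            f"where sampling is optimal; increase dv_max")
    v0 = float(V0_grid[nb, nb])
    return Policy(actions=actions, values=V0_grid, dv_grid=dv_grid, rho=rho,
                  config=config, v0=v0, max_leak=max_leak)


def find_rho(config: MDPConfig, tol: float = 1e-6, lo: float = 0.0,
             hi: Optional[float] = None, max_iter: int = 80,
             max_expansions: int = 2) -> Policy:
    """Bisection on rho so that the initial state's value is (near) zero.

    If the converged policy still moves appreciable belief-changing
    transition mass off the DV grid, the grid is widened and the solve
    repeated (up to ``max_expansions`` times).
    """
    if hi is None:
        hi = max(config.rc, config.rn, 0.1) / (config.tnd_mean + config.tw)
    p_lo = solve_bellman(config, lo)
    p_hi = solve_bellman(config, hi)
    if p_lo.v0 < 0 or p_hi.v0 > 0:
        if abs(p_lo.v0) < tol:
            return p_lo
        raise ValueError(f"rho bracket [{lo}, {hi}] does not straddle the "
                         f"root: V(s0) = {p_lo.v0:.4g}, {p_hi.v0:.4g}")
    pol = p_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        pol = solve_bellman(config, mid)
        if abs(pol.v0) < tol:
            try:
                return solve_bellman(config, mid, check_leak=True)
            except RuntimeError:
                if max_expansions <= 0:
                    raise
                import dataclasses
                wider = dataclasses.replace(config, dv_max=2 * config.dv_max)
                return find_rho(wider, tol=tol, lo=lo, hi=hi,
                                max_iter=max_iter,
                                max_expansions=max_expansions - 1)
        # keep the half with the sign change
        if pol.v0 > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"rho bisection did not reach |V(s0)| < {tol}; "
                       f"last V(s0) = {pol.v0:.3g}")


def simulate_policy(policy: Policy, conditions: Sequence[tuple[float, float]],
                    n: int, seed: int) -> pd.DataFrame:
    """Simulate trials that follow the optimal policy.

    ``conditions`` are (c1_signed, c2_signed) pairs from the prior support.
    DVs evolve continuously with true-coherence Gaussian increments and are
    snapped to the nearest grid state for policy lookup (clamped, and
    flagged, when off-grid). RT adds the mean non-decision time.
    """
    cfg = policy.config
    rng = np.random.default_rng(seed)
    N = len(policy.dv_grid)
    nb = N // 2
    K = policy.actions.shape[0] - 1
    rows = []
    for c1, c2 in conditions:
        dv1 = np.zeros(n)
        dv2 = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        choice = np.zeros(n, dtype=int)
        t_dec = np.zeros(n)
        clamped = np.zeros(n, dtype=bool)
        for k in range(K + 1):
            if not alive.any():
                break
            i1 = np.clip(np.round(dv1 / cfg.d_dv).astype(int) + nb, 0, N - 1)
            i2 = np.clip(np.round(dv2 / cfg.d_dv).astype(int) + nb, 0, N - 1)
            clamped |= alive & ((np.abs(dv1) > cfg.dv_max) |
                                (np.abs(dv2) > cfg.dv_max))
            act = policy.actions[k][i1, i2]
            for ch, code in ((1, CHOOSE_S1), (2, CHOOSE_S2)):
                sel = alive & (act == code)
                choice[sel] = ch
                t_dec[sel] = k * cfg.dt
                alive[sel] = False
            samp = alive & (act == SAMPLE)
            if k < K and samp.any():
                inc = rng.normal(0.0, np.sqrt(cfg.dt), size=int(samp.sum()))
                if k % 2 == 0:
                    dv1[samp] += cfg.kappa * c1 * cfg.dt + inc
                else:
                    dv2[samp] += cfg.kappa * c2 * cfg.dt + inc
        # anything still alive at the horizon: forced best choice
        if alive.any():
            i1 = np.clip(np.round(dv1 / cfg.d_dv).astype(int) + nb, 0, N - 1)
            i2 = np.clip(np.round(dv2 / cfg.d_dv).astype(int) + nb, 0, N - 1)
            act = policy.actions[K][i1, i2]
            choice[alive] = np.where(act[alive] == CHOOSE_S1, 1, 2)
            t_dec[alive] = K * cfg.dt
        s1, s2 = abs(c1), abs(c2)
        easier = 1 if s1 > s2 else (2 if s2 > s1 else 0)
        if easier == 0:
            corr = (choice == rng.integers(1, 3, size=n)).astype(int)
        else:
            corr = (choice == easier).astype(int)
        rows.append(pd.DataFrame({
            "c1_signed": c1, "c2_signed": c2, "choice": choice,
            "rt": t_dec + cfg.tnd_mean, "correct": corr,
            "clamped": clamped}))
    return pd.concat(rows, ignore_index=True)
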