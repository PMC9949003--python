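"""Drift-diffusion model of single-stimulus color judgments.

The decision variable is a Wiener process with drift ``kappa * (c + c0)``
and unit variance per second, absorbed at logistic collapsing bounds
``+/-B(t)``. Choice/decision-time distributions come from a Crank-Nicolson
finite-difference solution of the associated Fokker-Planck equation with
the time-varying absorbing boundary tracked on the grid; measured RT adds
a Gaussian non-decision time.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import optimize
from sklearn.base import BaseEstimator

from .params import ColorParams, SIGMA_TND
from ._kernels import _B_FLOOR

DEFAULT_FP_DT = 5e-4


def bound(t, u: float, a: float, d: float):
    """Logistic collapsing bound ``u / (1 + exp(a (t - d)))``.

    Equals ``u/2`` at ``t = d`` and approaches 0 as t grows (for a > 0).
    The numerical solvers additionally clip the bound below at a small
    epsilon to keep the absorbing problem well-posed.
    """
    z = np.clip(a * (np.asarray(t, dtype=float) - d), -700.0, 700.0)
    out = u / (1.0 + np.exp(z))
    return float(out) if np.isscalar(t) else out


@dataclass
class ChoiceRTDensity:
    """Joint density of (choice, decision time) on a uniform time grid."""

    t: np.ndarray        # time grid (s), step dt
    dt: float
    f_upper: np.ndarray  # absorbed-flux density at the upper (blue) bound
    f_lower: np.ndarray
    residual: float      # interior mass never absorbed within the horizon

    @property
    def p_upper(self) -> float:
        return float(self.f_upper.sum() * self.dt)

    @property
    def p_lower(self) -> float:
        return float(self.f_lower.sum() * self.dt)

    def mean_td(self, which: str = "both") -> float:
        if which == "upper":
            w = self.f_upper
        elif which == "lower":
            w = self.f_lower
        else:
            w = self.f_upper + self.f_lower
        return float((self.t * w).sum() / w.sum())


@njit(cache=True)
def _fp_loop(p, x, mu, dt, h, bvals, theta):
    """Theta-scheme sweep with absorption outside the collapsing bound.

    ``p`` holds node masses (sums to 1). ``theta`` = 1 is implicit Euler
    (L-stable: no oscillation at the absorption cliff the bound re-creates
    every step), 0.5 is Crank-Nicolson. Returns per-step absorbed mass at
    the upper/lower bound and the final interior mass.
    """
    n = p.shape[0]
    n_steps = bvals.shape[0]
    g_up = np.zeros(n_steps)
    g_lo = np.zeros(n_steps)
    # L p = -mu p_x + 0.5 p_xx, central differences
    alpha_c = theta * dt * 0.5 * (-mu) / h          # implicit advection
    beta_c = theta * dt * 0.5 / (h * h)             # implicit diffusion
    alpha_e = (1.0 - theta) * dt * 0.5 * (-mu) / h  # explicit advection
    beta_e = (1.0 - theta) * dt * 0.5 / (h * h)
    lo_c = -(-alpha_c + beta_c)            # implicit sub-diagonal
    di_c = 1.0 + 2.0 * beta_c
    up_c = -(alpha_c + beta_c)
    lo_e = -alpha_e + beta_e               # explicit sub-diagonal
    di_e = 1.0 - 2.0 * beta_e
    up_e = alpha_e + beta_e
    rhs = np.empty(n)
    cp = np.empty(n)
    for k in range(n_steps):
        s0 = 0.0
        for i in range(n):
            s0 += p[i]
        # explicit half step
        rhs[0] = di_e * p[0] + up_e * p[1]
        for i in range(1, n - 1):
            rhs[i] = lo_e * p[i - 1] + di_e * p[i] + up_e * p[i + 1]
        rhs[n - 1] = lo_e * p[n - 2] + di_e * p[n - 1]
        # Thomas solve of the implicit half step
        cp[0] = up_c / di_c
        rhs[0] = rhs[0] / di_c
        for i in range(1, n):
            m = di_c - lo_c * cp[i - 1]
            cp[i] = up_c / m
            rhs[i] = (rhs[i] - lo_c * rhs[i - 1]) / m
        p[n - 1] = rhs[n - 1]
        for i in range(n - 2, -1, -1):
            p[i] = rhs[i] - cp[i] * p[i + 1]
        s1 = 0.0
        for i in range(n):
            s1 += p[i]
        # absorb mass at/beyond the current bound
        B = bvals[k]
        for i in range(n):
            if x[i] >= B:
                if p[i] > 0.0:
                    g_up[k] += p[i]
                p[i] = 0.0
            elif x[i] <= -B:
                if p[i] > 0.0:
                    g_lo[k] += p[i]
                p[i] = 0.0
        # mass that diffused past the grid edge this step already crossed
        # the bound; credit it to the absorbing side(s)
        lost = s0 - s1
        if lost > 0.0:
            tot = g_up[k] + g_lo[k]
            if tot > 0.0:
                g_up[k] += lost * g_up[k] / tot
                g_lo[k] += lost * g_lo[k] / tot
            else:
                g_up[k] += 0.5 * lost
                g_lo[k] += 0.5 * lost
    interior = 0.0
    for i in range(n):
        interior += p[i]
    return g_up, g_lo, interior


def fp_solve(params: ColorParams, c_signed: float, dt: float = DEFAULT_FP_DT,
             horizon: float = 8.0, n_grid: int = 441, theta: float = 0.5,
             check: bool = True, residual_tol: float = 1e-3) -> ChoiceRTDensity:
    """Choice/decision-time distributions for one signed coherence.

    The drift is ``kappa * (c_signed + c0)`` (the bias acts as a coherence
    offset). The evidence grid spans +/-1.05 u with >= 200 interior points
    across 2u; probability conservation (absorbed + interior = 1) holds to
    solver precision at every step.
    """
    mu = params.kappa * (c_signed + params.c0)
    xmax = 1.05 * params.u
    n_grid = int(n_grid) | 1  # odd: a node exactly at 0
    x = np.linspace(-xmax, xmax, n_grid)
    h = x[1] - x[0]
    n_steps = int(round(horizon / dt))
    tgrid = (np.arange(n_steps) + 1) * dt
    bvals = np.maximum(bound(tgrid, params.u, params.a, params.d), _B_FLOOR)
    # exact free-diffusion solution for the first step: starting from the
    # resolved Gaussian (rather than a grid delta) avoids Crank-Nicolson
    # startup oscillation at strong drift
    p = np.exp(-0.5 * (x - mu * dt) ** 2 / dt)
    p /= p.sum()
    g_up = np.zeros(n_steps)
    g_lo = np.zeros(n_steps)
    up0 = x >= bvals[0]
    lo0 = x <= -bvals[0]
    g_up[0] = p[up0].sum()
    g_lo[0] = p[lo0].sum()
    p[up0 | lo0] = 0.0
    gu, gl, interior = _fp_loop(p, x, mu, dt, h, bvals[1:], theta)
    g_up[1:] = gu
    g_lo[1:] = gl
    if check and interior > residual_tol:
        raise RuntimeError(
            f"Fokker-Planck solve left {interior:.3g} interior mass at the "
            f"horizon {horizon} s; increase horizon or loosen the bound")
    return ChoiceRTDensity(t=tgrid, dt=dt, f_upper=g_up / dt, f_lower=g_lo / dt,
                           residual=float(interior))


def rt_distribution(density: ChoiceRTDensity, tnd: float,
                    sigma_tnd: float = SIGMA_TND):
    """Convolve the decision-time density with the non-decision time.

    Returns ``(t, f_upper, f_lower)`` on an extended grid. The convolution
    kernel is Normal(tnd, sigma_tnd^2); mass falling at rt <= 0 is dropped
    and each choice's density renormalized to preserve its total choice
    probability.
    """
    dt = density.dt
    if sigma_tnd < dt / 2:
        # effectively a pure shift
        shift = int(round(tnd / dt))
        n = density.t.shape[0] + shift
        t = (np.arange(n) + 1) * dt
        fu = np.zeros(n)
        fl = np.zeros(n)
        fu[shift:] = density.f_upper
        fl[shift:] = density.f_lower
        return t, fu, fl
    lo = tnd - 5 * sigma_tnd
    hi = tnd + 5 * sigma_tnd
    offs = np.arange(math.floor(lo / dt), math.ceil(hi / dt) + 1)
    kern = np.exp(-0.5 * ((offs * dt - tnd) / sigma_tnd) ** 2)
    kern /= kern.sum()
    n_in = density.t.shape[0]
    k0 = offs[0]
    n_out = n_in + offs[-1]
    fu = np.zeros(n_out)
    fl = np.zeros(n_out)
    for j, w in enumerate(kern):
        off = int(offs[j])
        src_u = density.f_upper * w
        src_l = density.f_lower * w
        a = off  # target index offset (time index i + off)
        lo_t = max(0, -a)
        hi_t = min(n_in, n_out - a)
        if hi_t > lo_t:
            fu[lo_t + a:hi_t + a] += src_u[lo_t:hi_t]
            fl[lo_t + a:hi_t + a] += src_l[lo_t:hi_t]
    t = (np.arange(n_out) + 1) * dt
    pos = t > 0
    for f, tot in ((fu, density.p_upper), (fl, density.p_lower)):
        s = f[pos].sum() * dt
        if s > 0 and tot > 0:
            f *= tot / s
    return t[pos], fu[pos], fl[pos]


_COLOR_BOUNDS = [(0.5, 40.0), (-0.3, 0.3), (0.1, 10.0), (-5.0, 10.0),
                 (-2.0, 10.0), (0.05, 1.0)]


def color_loglik(theta: np.ndarray, coh: np.ndarray, obs_by_coh: list,
                 dt: float, horizon: float, lik_floor: float = 1e-10) -> float:
    """Log-likelihood of color-task (choice, rt) data for one parameter vector."""
    kappa, c0, u, a, d, tnd = theta
    try:
        params = ColorParams(kappa=kappa, c0=c0, u=u, a=a, d=d, tnd=tnd)
    except ValueError:
        return -np.inf
    total = 0.0
    for ci, c in enumerate(coh):
        rts, choices = obs_by_coh[ci]
        if len(rts) == 0:
            continue
        dens = fp_solve(params, c, dt=dt, horizon=horizon, check=False)
        t, fu, fl = rt_distribution(dens, tnd)
        fu_obs = np.interp(rts, t, fu, left=0.0, right=0.0)
        fl_obs = np.interp(rts, t, fl, left=0.0, right=0.0)
        f = np.where(choices == 1, fu_obs, fl_obs)
        total += float(np.log(np.maximum(f, lik_floor)).sum())
    return total


class ColorDDM(BaseEstimator):
    """Maximum-likelihood color DDM, scikit-learn estimator style.

    Parameters are optimized by bounded Nelder-Mead from ``n_starts``
    seeded starting points. After ``fit``, the fitted parameters are in
    ``params_`` and the best log-likelihood in ``loglik_``.
    """

    def __init__(self, n_starts: int = 10, dt: float = 1e-3,
                 horizon: float = 8.0, max_evals: int = 200,
                 random_state: int = 0):
        self.n_starts = n_starts
        self.dt = dt
        self.horizon = horizon
        self.max_evals = max_evals
        self.random_state = random_state

    def fit(self, trials) -> "ColorDDM":
        trials = trials[trials["task"] == "color_rt"]
        if len(trials) == 0:
            raise ValueError("no color-task trials to fit")
        coh = np.sort(trials["c1_signed"].unique())
        obs_by_coh = []
        for c in coh:
            sub = trials[trials["c1_signed"] == c]
            obs_by_coh.append((sub["rt"].to_numpy(float),
                               sub["choice"].to_numpy(int)))

        rng = np.random.default_rng(self.random_state)
        lo = np.array([b[0] for b in _COLOR_BOUNDS])
        hi = np.array([b[1] for b in _COLOR_BOUNDS])
        span = hi - lo

        def neg(z):
            theta = lo + np.clip(z, 0.0, 1.0) * span
            return -color_loglik(theta, coh, obs_by_coh, self.dt, self.horizon)

        start0 = np.array([8.0, 0.0, 1.0, 2.0, 1.0,
                           max(0.06, 0.8 * trials["rt"].min())])
        unit = [(0.0, 1.0)] * len(lo)
        best = None
        self.trace_ = []
        for s in range(self.n_starts):
            z0 = (start0 - lo) / span if s == 0 else rng.uniform(0.1, 0.9,
                                                                 len(lo))
            res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                    bounds=unit,
                                    options={"maxfev": self.max_evals,
                                             "adaptive": True,
                                             "xatol": 1e-4, "fatol": 0.01})
            self.trace_.append({"start": s, "loglik": -float(res.fun),
                                "nfev": res.nfev})
            if best is None or res.fun < best.fun:
                best = res
        th = lo + np.clip(best.x, 0.0, 1.0) * span
        self.params_ = ColorParams(kappa=th[0], c0=th[1], u=th[2], a=th[3],
                                   d=th[4], tnd=th[5])
        self.loglik_ = -float(best.fun)
        self.n_trials_ = len(trials)
        self.at_bounds_ = bool(np.any(np.isclose(th, lo)) or
                               np.any(np.isclose(th, hi)))
        return self


def fit_color(trials, starts: int = 10, seed: int = 0, **kw):
    """Functional wrapper over :class:`ColorDDM`."""
    est = ColorDDM(n_starts=starts, random_state=seed, **kw)
    est.fit(trials)
    return est.params_, est.loglik_
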