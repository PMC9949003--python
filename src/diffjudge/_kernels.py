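"""Numba kernels for the diffusion simulators and kernel-density likelihood.

All simulators share the serial, time-multiplexed accumulation scheme:
stimulus S1 receives the evidence increment on even steps and S2 on odd
steps, so each stimulus is sampled for half of the elapsed decision time.
Increments over a step of ``dt`` are ``kappa * c * dt + Normal(0, dt)``.

Model ids: 0 race, 1 difference, 2 two-step, 3 absolute momentary evidence,
4 signed difference (known color), 5 confidence (unknown), 6 confidence
(known color).
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

RACE, DIFFERENCE, TWO_STEP, ABS_MOMENTARY, DIFF_KNOWN, CONF_UNKNOWN, CONF_KNOWN = range(7)

_B_FLOOR = 1e-3  # keeps the absorbing problem well-posed for collapsed bounds
_BMINI_FLAT = 2.0  # the mini-decision bound is flat for 2 s, then collapses to 0


@njit(cache=True, fastmath=True)
def _bound(t, u, a, d):
    z = a * (t - d)
    if z > 700.0:
        z = 700.0
    elif z < -700.0:
        z = -700.0
    b = u / (1.0 + math.exp(z))
    return b if b > _B_FLOOR else _B_FLOOR


@njit(cache=True, fastmath=True)
def _logodds(dv, t, kappa, levels):
    """Log-odds that sign(coherence) matches sign(dv), uniform prior on levels.

    ``levels`` holds the 12 signed coherences, the first half negative. The
    common factor exp(-dv^2 / 2t) / sqrt(2 pi t) cancels between numerator
    and denominator, leaving weights exp(dv*kappa*c - (kappa*c)^2 * t / 2).
    """
    if t <= 0.0:
        return 0.0
    n = levels.shape[0]
    half = n // 2
    mx = -1e300
    w = np.empty(n)
    for i in range(n):
        kc = kappa * levels[i]
        w[i] = dv * kc - 0.5 * kc * kc * t
        if w[i] > mx:
            mx = w[i]
    sneg = 0.0
    spos = 0.0
    for i in range(n):
        e = math.exp(w[i] - mx)
        if i < half:
            sneg += e
        else:
            spos += e
    # log-odds for a blue (positive) choice; symmetric for yellow
    lo_pos = math.log(spos) - math.log(sneg)
    if dv >= 0.0:
        return lo_pos
    return -lo_pos


@njit(cache=True, fastmath=True)
def _sign_or_random(x):
    if x > 0.0:
        return 1.0
    if x < 0.0:
        return -1.0
    return 1.0 if np.random.random() < 0.5 else -1.0


@njit(cache=True, fastmath=True)
def simulate_rt_models(model_id, c1_arr, c2_arr, known_sign_arr, n_per_cond,
                       kappa, u, a, d, b_mini, dt, horizon, levels, seed,
                       noise):
    """Simulate ``n_per_cond`` decision trials for every condition.

    Returns (choice, td, censored) arrays of length n_cond * n_per_cond,
    condition-major. ``choice`` is 1 (S1 easier) or 2 (S2 easier); ``td`` is
    the decision time (s); censored trials ran to the horizon unabsorbed and
    carry the sign of the decision quantity at the horizon.

    ``noise``: optional pre-generated N(0,1) pool (power-of-two length).
    When non-empty, each trial reads a hashed-offset slice of the pool
    instead of drawing fresh variates — much faster, and gives common
    random numbers across repeated calls with the same seed. An empty
    array selects fresh per-step draws (used for data generation).
    """
    np.random.seed(seed)
    n_cond = c1_arr.shape[0]
    n_steps = int(round(horizon / dt))
    sqdt = math.sqrt(dt)
    ntot = n_cond * n_per_cond
    choice = np.zeros(ntot, dtype=np.int8)
    td = np.zeros(ntot)
    censored = np.zeros(ntot, dtype=np.bool_)
    use_pool = noise.shape[0] > 0
    pool_mask = noise.shape[0] - 1

    bounds = np.empty(n_steps)
    for k in range(n_steps):
        bounds[k] = _bound((k + 1) * dt, u, a, d)

    for ci in range(n_cond):
        c1 = c1_arr[ci]
        c2 = c2_arr[ci]
        ks = known_sign_arr[ci]
        for i in range(n_per_cond):
            idx = ci * n_per_cond + i
            pidx = (idx * 2654435761 + seed) & pool_mask
            # which stimulus is sampled first alternates randomly by trial,
            # so the two stimuli are exchangeable in distribution
            first = 0 if np.random.random() < 0.5 else 1
            dv1 = 0.0
            dv2 = 0.0
            lo1 = 0.0
            lo2 = 0.0
            have_mini = model_id != TWO_STEP
            s1 = 0.0
            s2 = 0.0
            done = False
            x = 0.0
            for k in range(n_steps):
                t = (k + 1) * dt
                if use_pool:
                    z = noise[pidx]
                    pidx = (pidx + 1) & pool_mask
                else:
                    z = np.random.normal(0.0, 1.0)
                eps = z * sqdt
                if (k + first) % 2 == 0:
                    inc = kappa * c1 * dt + eps
                    if model_id == ABS_MOMENTARY:
                        inc = abs(inc)
                    dv1 += inc
                    if model_id == CONF_UNKNOWN or model_id == CONF_KNOWN:
                        lo1 = _logodds(dv1, (k // 2 + 1) * dt, kappa, levels)
                else:
                    inc = kappa * c2 * dt + eps
                    if model_id == ABS_MOMENTARY:
                        inc = abs(inc)
                    dv2 += inc
                    if model_id == CONF_UNKNOWN or model_id == CONF_KNOWN:
                        lo2 = _logodds(dv2, (k // 2 + 1) * dt, kappa, levels)
                B = bounds[k]
                if model_id == TWO_STEP and not have_mini:
                    bm = b_mini if t < _BMINI_FLAT else 0.0
                    if abs(dv1) >= bm or abs(dv2) >= bm:
                        have_mini = True
                        s1 = _sign_or_random(dv1)
                        s2 = _sign_or_random(dv2)
                if model_id == RACE:
                    e1 = abs(dv1) - B
                    e2 = abs(dv2) - B
                    if e1 >= 0.0 or e2 >= 0.0:
                        if e1 >= 0.0 and e2 >= 0.0:
                            if e1 > e2:
                                choice[idx] = 1
                            elif e2 > e1:
                                choice[idx] = 2
                            else:
                                choice[idx] = 1 if np.random.random() < 0.5 else 2
                        elif e1 >= 0.0:
                            choice[idx] = 1
                        else:
                            choice[idx] = 2
                        td[idx] = t
                        done = True
                        break
                    continue
                if model_id == DIFFERENCE:
                    x = abs(dv1) - abs(dv2)
                elif model_id == TWO_STEP:
                    if not have_mini:
                        continue
                    x = s1 * dv1 - s2 * dv2
                elif model_id == ABS_MOMENTARY:
                    x = dv1 - dv2
                elif model_id == DIFF_KNOWN:
                    x = ks * (dv1 - dv2)
                elif model_id == CONF_UNKNOWN:
                    x = abs(lo1) - abs(lo2)
                else:  # CONF_KNOWN
                    x = ks * (lo1 - lo2)
                if x >= B:
                    choice[idx] = 1
                    td[idx] = t
                    done = True
                    break
                if x <= -B:
                    choice[idx] = 2
                    td[idx] = t
                    done = True
                    break
            if not done:
                censored[idx] = True
                td[idx] = n_steps * dt
                if model_id == RACE:
                    x = abs(dv1) - abs(dv2)
                s = _sign_or_random(x)
                choice[idx] = 1 if s > 0.0 else 2
    return choice, td, censored


@njit(cache=True, fastmath=True)
def simulate_cd_models(known_flags, c1_arr, c2_arr, known_sign_arr, dur_arr,
                       n_per_cond, kappa, u, a, d, dt, t_buf, seed, noise):
    """Controlled-duration simulator (choices only).

    Both streams accumulate in parallel while the stimulus time is within
    the sensory buffer; afterwards accumulation alternates. The collapsing
    bound runs on stimulus time. If no bound is crossed by stimulus offset,
    the choice is the sign of the decision quantity at the end.
    Returns (choice, crossed) arrays, condition-major. ``noise`` as in
    :func:`simulate_rt_models`.
    """
    np.random.seed(seed)
    n_cond = c1_arr.shape[0]
    sqdt = math.sqrt(dt)
    ntot = n_cond * n_per_cond
    choice = np.zeros(ntot, dtype=np.int8)
    crossed = np.zeros(ntot, dtype=np.bool_)
    n_buf = int(round(t_buf / dt))
    use_pool = noise.shape[0] > 0
    pool_mask = noise.shape[0] - 1
    for ci in range(n_cond):
        c1 = c1_arr[ci]
        c2 = c2_arr[ci]
        ks = known_sign_arr[ci]
        known = known_flags[ci]
        n_steps = int(round(dur_arr[ci] / dt))
        for i in range(n_per_cond):
            idx = ci * n_per_cond + i
            pidx = (idx * 2654435761 + seed) & pool_mask
            first = 0 if np.random.random() < 0.5 else 1
            dv1 = 0.0
            dv2 = 0.0
            done = False
            x = 0.0
            for k in range(n_steps):
                t = (k + 1) * dt
                if use_pool:
                    z1 = noise[pidx]
                    pidx = (pidx + 1) & pool_mask
                else:
                    z1 = np.random.normal(0.0, 1.0)
                if k < n_buf:
                    if use_pool:
                        z2 = noise[pidx]
                        pidx = (pidx + 1) & pool_mask
                    else:
                        z2 = np.random.normal(0.0, 1.0)
                    dv1 += kappa * c1 * dt + z1 * sqdt
                    dv2 += kappa * c2 * dt + z2 * sqdt
                else:
                    if (k - n_buf + first) % 2 == 0:
                        dv1 += kappa * c1 * dt + z1 * sqdt
                    else:
                        dv2 += kappa * c2 * dt + z1 * sqdt
                if known:
                    x = ks * (dv1 - dv2)
                else:
                    x = abs(dv1) - abs(dv2)
                B = _bound(t, u, a, d)
                if x >= B or x <= -B:
                    choice[idx] = 1 if x >= B else 2
                    crossed[idx] = True
                    done = True
                    break
            if not done:
                s = _sign_or_random(x)
                choice[idx] = 1 if s > 0.0 else 2
    return choice, crossed


@njit(cache=True, fastmath=True)
def _silverman_bw(x, floor):
    m = x.shape[0]
    if m < 2:
        return floor
    mu = 0.0
    for v in x:
        mu += v
    mu /= m
    ss = 0.0
    for v in x:
        ss += (v - mu) ** 2
    sd = math.sqrt(ss / (m - 1))
    xs = np.sort(x)
    q1 = xs[int(0.25 * (m - 1))]
    q3 = xs[int(0.75 * (m - 1))]
    iqr = q3 - q1
    spread = sd
    if iqr > 0.0 and iqr / 1.34 < spread:
        spread = iqr / 1.34
    h = 0.9 * spread * m ** (-0.2)
    return h if h > floor else floor


@njit(cache=True, fastmath=True)
def epanechnikov_loglik(obs_rt, obs_choice, obs_cond, n_cond,
                        sim_rt, sim_choice, sim_censored, n_sim_per_cond,
                        bw_floor, mix_mass, mix_dens):
    """Sum of log joint densities p(choice, rt) of observed trials.

    For each condition and choice, an Epanechnikov kernel density is fit to
    the non-censored simulated RTs of that choice, scaled by the simulated
    probability of the choice. The kernel density is mixed with a small
    uniform contaminant (``mix_mass`` of total mass at density
    ``mix_dens``), so observed tail RTs falling into kernel gaps are
    penalized smoothly instead of hitting a hard floor; trials whose choice
    has no simulated mass score the contaminant density alone.
    """
    total = 0.0
    log_mix = math.log(mix_mass * mix_dens)
    for ci in range(n_cond):
        base = ci * n_sim_per_cond
        # collect valid sims for this condition by choice
        n_valid = 0
        for j in range(n_sim_per_cond):
            if not sim_censored[base + j]:
                n_valid += 1
        for ch in range(1, 3):
            m = 0
            for j in range(n_sim_per_cond):
                jj = base + j
                if sim_choice[jj] == ch and not sim_censored[jj]:
                    m += 1
            n_obs_ch = 0
            for oi in range(obs_rt.shape[0]):
                if obs_cond[oi] == ci and obs_choice[oi] == ch:
                    n_obs_ch += 1
            if n_obs_ch == 0:
                continue
            if m == 0 or n_valid == 0:
                total += n_obs_ch * log_mix
                continue
            rts = np.empty(m)
            p = 0
            for j in range(n_sim_per_cond):
                jj = base + j
                if sim_choice[jj] == ch and not sim_censored[jj]:
                    rts[p] = sim_rt[jj]
                    p += 1
            h = _silverman_bw(rts, bw_floor)
            for oi in range(obs_rt.shape[0]):
                if obs_cond[oi] != ci or obs_choice[oi] != ch:
                    continue
                r = obs_rt[oi]
                s = 0.0
                for j in range(m):
                    z = (r - rts[j]) / h
                    if -1.0 < z < 1.0:
                        s += 0.75 * (1.0 - z * z)
                dens = s / (n_valid * h)
                total += math.log((1.0 - mix_mass) * dens
                                  + mix_mass * mix_dens)
    return total
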