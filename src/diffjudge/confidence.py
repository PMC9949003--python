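"""Difficulty as a comparison of color-choice confidence.

Confidence here is the running log-odds that a color choice made from the
sign of the current DV would be correct, computed by Bayes over the
discrete set of signed coherences. The difficulty decision bounds the
difference of the two stimuli's (absolute or sign-corrected) log-odds with
the same collapsing bound, serial sampling and non-decision time as the
Difference model. Each stimulus's confidence uses the time that stimulus
was actually sampled (half the elapsed decision time under serial sharing).
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import DifficultyParams, signed_levels
from .simulate import simulate_model


def logodds_correct(dv, t_stim, kappa: float,
                    prior: Optional[np.ndarray] = None):
    """Log-odds that sign(coherence) matches sign(dv) after ``t_stim`` s.

    The posterior over signed coherences is proportional to
    ``Normal(dv | kappa*c*t, t) * P(c)`` with a uniform prior over the 12
    signed levels by default (+0 and -0 are distinct, numerically equal).
    At ``t_stim = 0`` this is the log-odds of the prior mass on the
    matching sign (0 for a sign-symmetric prior). Even in ``dv``.
    """
    levels = np.asarray(signed_levels() if prior is None else prior, float)
    half = len(levels) // 2
    dv = np.asarray(dv, dtype=float)
    t = np.asarray(t_stim, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_stim must be >= 0")
    scalar = dv.ndim == 0 and t.ndim == 0
    dv, t = np.atleast_1d(dv), np.atleast_1d(t)
    dv, t = np.broadcast_arrays(dv, t)
    kc = kappa * levels
    with np.errstate(divide="ignore"):
        # common exp(-dv^2/2t)/sqrt(2 pi t) factor cancels in the odds
        logw = np.where(t[..., None] > 0,
                        dv[..., None] * kc - 0.5 * kc ** 2 * t[..., None],
                        0.0)
    mx = logw.max(axis=-1, keepdims=True)
    w = np.exp(logw - mx)
    s_neg = w[..., :half].sum(axis=-1)
    s_pos = w[..., half:].sum(axis=-1)
    lo_pos = np.log(s_pos) - np.log(s_neg)
    out = np.where(dv >= 0, lo_pos, -lo_pos)
    return float(out[0]) if scalar else out


def prob_correct(dv, t_stim, kappa: float) -> np.ndarray:
    """Raw probability version of :func:`logodds_correct`."""
    lo = logodds_correct(dv, t_stim, kappa)
    return 1.0 / (1.0 + np.exp(-np.asarray(lo)))


def simulate_confidence_model(params: DifficultyParams, conditions: Sequence,
                              n: int, seed: int, known: bool = False,
                              **kw) -> pd.DataFrame:
    """Simulate the difference-in-confidence model.

    Unknown color: terminate when |log-odds(S1)| - |log-odds(S2)| crosses
    +/-B(t). Known color: the difference of the appropriately signed
    log-odds (log-odds of choosing the known color) is bounded instead.
    """
    model = "confidence_known" if known else "confidence"
    return simulate_model(model, params, conditions, n, seed, **kw)
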