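"""Generate-fit-classify model recovery.

Synthetic data sets are simulated per subject from a generating model and
parameter set, every candidate model is fit to each data set, and the data
set is classified either by lowest BIC or by a |dBIC| > threshold rule
(which can leave a data set undecided when no model clears the margin).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import make_design
from .fitting import DifficultyModel, FitResult
from .params import DifficultyParams
from .simulate import simulate_model

DEFAULT_MODELS = ("race", "difference", "two_step", "abs_momentary")


@dataclass
class RecoveryReport:
    """Outcome of one recovery run for one generating model."""

    generating_model: str
    models: tuple
    rule: str
    threshold: float
    classifications: list = field(default_factory=list)  # winner per dataset
    bics: list = field(default_factory=list)             # {model: bic} per dataset
    failures: int = 0
    seed: int = 0

    @property
    def n_datasets(self) -> int:
        return len(self.classifications)

    @property
    def n_correct(self) -> int:
        return sum(c == self.generating_model for c in self.classifications)

    @property
    def n_undecided(self) -> int:
        return sum(c == "undecided" for c in self.classifications)

    @property
    def accuracy(self) -> float:
        return self.n_correct / max(self.n_datasets, 1)

    def confusion_row(self) -> dict:
        counts = {m: 0 for m in self.models}
        counts["undecided"] = 0
        for c in self.classifications:
            counts[c] += 1
        return counts

    def to_dict(self) -> dict:
        return {
            "generating_model": self.generating_model,
            "models": list(self.models),
            "rule": self.rule,
            "threshold": self.threshold,
            "classifications": self.classifications,
            "bics": self.bics,
            "accuracy": self.accuracy,
            "n_undecided": self.n_undecided,
            "failures": self.failures,
            "seed": self.seed,
        }


def _classify(bics: dict, rule: str, threshold: float) -> str:
    order = sorted(bics.items(), key=lambda kv: kv[1])
    if rule == "lowest_bic":
        return order[0][0]
    if rule == "delta_bic_threshold":
        if len(order) > 1 and order[1][1] - order[0][1] > threshold:
            return order[0][0]
        return "undecided"
    raise ValueError(f"unknown classification rule {rule!r}")


def recover(generating_params: Sequence[DifficultyParams],
            generating_model: str = "difference",
            models: Sequence[str] = DEFAULT_MODELS,
            datasets_per_subject: int = 10,
            trials_per_dataset: int = 1152,
            rule: str = "lowest_bic",
            threshold: float = 10.0,
            seed: int = 0,
            n_sim: int = 1000,
            n_sim_explore: int = 250,
            n_starts: int = 10,
            max_evals: int = 300,
            polish_evals: int = 80,
            scale: float = 1.0,
            task: str = "difficulty_rt_unknown") -> RecoveryReport:
    """Run the recovery protocol.

    ``scale`` < 1 uniformly shrinks datasets-per-subject, fit simulation
    counts, restarts and optimizer evaluations for smoke runs. Trial counts
    default to the full reaction-time experiment (1,152 per data set,
    equal-strength pairs at one third frequency). Fit failures are recorded
    and the data set excluded.
    """
    if scale != 1.0:
        datasets_per_subject = max(1, int(round(datasets_per_subject * scale)))
        n_sim = max(100, int(round(n_sim * scale)))
        n_starts = max(1, int(round(n_starts * scale)))
        max_evals = max(50, int(round(max_evals * scale)))
    freq = 1.0 / 3.0  # equal-strength pairs shown at one third frequency
    base = len(make_design(task, 1, 1.0))
    r0 = max(1, int(round(trials_per_dataset / base)))
    reps = min(range(max(1, r0 - 3), r0 + 4),
               key=lambda r: abs(len(make_design(task, r, freq))
                                 - trials_per_dataset))
    design = make_design(task, reps=reps, equal_strength_frequency=freq)
    report = RecoveryReport(generating_model=generating_model,
                            models=tuple(models), rule=rule,
                            threshold=threshold, seed=seed)
    ss = np.random.SeedSequence(seed)
    for si, params in enumerate(generating_params):
        for di in range(datasets_per_subject):
            data_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31 - 1))
            data = simulate_model(generating_model, params, design, n=1,
                                  seed=data_seed, subject=si)
            data = data[~data["censored"]].reset_index(drop=True)
            bics = {}
            try:
                for m in models:
                    est = DifficultyModel(model=m, n_sim=n_sim,
                                          n_sim_explore=n_sim_explore,
                                          n_starts=n_starts,
                                          max_evals=max_evals,
                                          polish_evals=polish_evals,
                                          random_state=data_seed + 1)
                    est.fit(data)
                    bics[m] = float(est.bic_)
            except RuntimeError:
                report.failures += 1
                continue
            report.bics.append(bics)
            report.classifications.append(_classify(bics, rule, threshold))
    return report


def confusion_matrix(reports: Sequence[RecoveryReport]) -> pd.DataFrame:
    """Rows: generating model; columns: classified model (plus undecided)."""
    rows = {r.generating_model: r.confusion_row() for r in reports}
    return pd.DataFrame(rows).T.fillna(0).astype(int)
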