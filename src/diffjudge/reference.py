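"""Published per-subject Difference-model parameters (20 subjects).

These maximum-likelihood fits of the Difference model to the reaction-time
difficulty task serve as the package's generative ground truth: synthetic
subjects are simulated from them for parameter-recovery and model-recovery
studies. Columns: kappa, u, a, d, tnd.
"""
from __future__ import annotations

from .params import DifficultyParams

_TABLE = [
    # kappa, u,    a,     d,     tnd
    (6.37, 0.97, 4.46, 1.16, 0.34),
    (5.21, 1.11, 3.73, 1.37, 0.36),
    (7.78, 0.59, 4.99, 3.40, 0.39),
    (5.97, 1.00, -0.87, -0.77, 0.38),
    (6.24, 2.31, 1.59, -0.21, 0.34),
    (4.20, 1.59, 1.52, 1.72, 0.34),
    (5.87, 2.13, 0.77, -0.06, 0.39),
    (4.87, 2.24, 0.42, -0.43, 0.20),
    (5.20, 1.30, -0.14, 1.05, 0.41),
    (6.40, 1.23, 4.13, 1.37, 0.34),
    (5.14, 1.25, 4.36, 1.75, 0.14),
    (4.70, 2.03, 1.12, 0.88, 0.33),
    (6.25, 1.14, 4.25, 1.46, 0.47),
    (4.88, 2.30, 0.76, 0.02, 0.23),
    (5.65, 0.87, 4.88, 1.54, 0.26),
    (4.38, 1.47, 4.64, 1.70, 0.24),
    (5.21, 0.87, 0.91, 1.34, 0.42),
    (4.89, 0.97, 5.00, 1.61, 0.33),
    (5.05, 1.05, 3.17, 0.67, 0.40),
    (5.07, 1.41, 0.81, 1.53, 0.33),
]

#: Per-subject Difference-model parameters, subjects 1..20.
REFERENCE_PARAMS: list[DifficultyParams] = [
    DifficultyParams(kappa=k, u=u, a=a, d=d, tnd=t) for k, u, a, d, t in _TABLE
]

#: Across-subject mean parameters (kappa=5.47, u=1.39, a=2.52, d=1.06, tnd=0.33).
MEAN_PARAMS = DifficultyParams(kappa=5.47, u=1.39, a=2.52, d=1.06, tnd=0.33)
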