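"""Parameter containers for the diffusion models.

All models share the evidence-accumulation convention that momentary
evidence for a stimulus of signed coherence ``c`` over a step ``dt`` is
``kappa * c * dt + Normal(0, dt)``, i.e. the decision variable has unit
diffusion variance per second of sampling.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Optional

#: Fixed standard deviation of the non-decision time (s).
SIGMA_TND = 0.05

#: Signed coherence levels used throughout: +/- {0, .128, .256, .384, .512, .64}.
STRENGTH_LEVELS = (0.0, 0.128, 0.256, 0.384, 0.512, 0.64)


def signed_levels() -> list[float]:
    """The 12 signed coherence levels (-0 and +0 are distinct conditions)."""
    return [-c for c in reversed(STRENGTH_LEVELS)] + list(STRENGTH_LEVELS)


@dataclass
class DifficultyParams:
    """Parameters of one difficulty-judgment model for one subject.

    Parameters
    ----------
    kappa : drift coefficient (evidence units / s / unit coherence).
    u, a, d : collapsing-bound parameters; the bound is
        ``B(t) = u / (1 + exp(a * (t - d)))``.
    tnd : mean non-decision time (s); sd fixed at ``SIGMA_TND``.
    b_mini : mini-decision bound height (Two-step model only).
    """

    kappa: float
    u: float
    a: float
    d: float
    tnd: float
    b_mini: Optional[float] = None

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError(f"bound height u must be positive, got {self.u}")
        if self.tnd <= 0:
            raise ValueError(f"non-decision time must be positive, got {self.tnd}")

    def to_json(self) -> str:
        return json.dumps({k: v for k, v in asdict(self).items() if v is not None})

    @classmethod
    def from_json(cls, s: str) -> "DifficultyParams":
        return cls(**json.loads(s))


@dataclass
class ColorParams:
    """Parameters of the single-stimulus color DDM.

    ``c0`` is a bias expressed as a coherence offset: the drift is
    ``kappa * (c_signed + c0)``.
    """

    kappa: float
    c0: float
    u: float
    a: float
    d: float
    tnd: float
    sigma_tnd: float = field(default=SIGMA_TND)

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError(f"bound height u must be positive, got {self.u}")
        if self.tnd <= 0:
            raise ValueError(f"non-decision time must be positive, got {self.tnd}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ColorParams":
        return cls(**json.loads(s))
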