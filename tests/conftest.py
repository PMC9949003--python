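import numpy as np
import pytest

from diffjudge import DifficultyParams
from diffjudge.design import make_design
from diffjudge.reference import REFERENCE_PARAMS, MEAN_PARAMS


@pytest.fixture(scope="session")
def mean_params() -> DifficultyParams:
    return MEAN_PARAMS


@pytest.fixture(scope="session")
def subject1_params() -> DifficultyParams:
    return REFERENCE_PARAMS[0]


@pytest.fixture(scope="session")
def rt_design():
    """Full 12 x 12 unknown-color reaction-time design, one rep."""
    return make_design("difficulty_rt_unknown", 1, 1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
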