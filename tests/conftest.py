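import numpy as np
import pytest

from circinf.ci_model import CIParams
from circinf.task import make_trial_sequence


@pytest.fixture(scope="session")
def default_seq():
    """The full 10-block x 64-trial sequence with 7 balanced delay levels."""
    return make_trial_sequence(seed=1)


@pytest.fixture(scope="session")
def small_seq():
    """A short sequence (4 blocks x 15 trials) for fast fitting tests."""
    return make_trial_sequence(n_blocks=4, trials_per_block=15, seed=2)


@pytest.fixture(scope="session")
def mean_params():
    """Population-mean circular-inference parameters at baseline."""
    return CIParams(b=0.59, w=1.70, loop_strength=1.85, penalty=-2.04)


@pytest.fixture()
def symmetric_leaky():
    """Unbiased leaky integrator: closed-form OFF decay applies."""
    return CIParams(b=0.5, w=0.0, loop_strength=0.0, penalty=0.0)


@pytest.fixture()
def bistable_params():
    """Strongly bistable symmetric model."""
    return CIParams(b=0.5, w=0.0, loop_strength=3.0, penalty=0.0)
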