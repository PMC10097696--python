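import numpy as np
import pytest

from repsim import AssessmentFrame, GameParams, Population


@pytest.fixture(scope="session")
def frame5():
    return AssessmentFrame.symmetric(5)


@pytest.fixture(scope="session")
def noisy_params():
    return GameParams(eps=0.05, q=0.9)


@pytest.fixture(scope="session")
def noise_free_params():
    return GameParams(eps=0.0, q=1.0)


@pytest.fixture
def small_mixed_population():
    return Population(["L1"] * 4 + ["ALLC"] * 2 + ["ALLD"] * 2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
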