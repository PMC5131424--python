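import numpy as np
import pytest

from codemort import CoDeParams, preset


def random_code_params(rng: np.random.Generator) -> CoDeParams:
    """Draw a valid CoDe parameter set in realistic low-mortality ranges."""
    return CoDeParams(
        A=rng.uniform(1e-4, 0.05),
        B=rng.uniform(0.1, 5.0),
        a=rng.uniform(1e-5, 0.01),
        b1=rng.uniform(0.05, 0.3),
        b2=rng.uniform(0.05, 0.3),
        b3=rng.uniform(0.05, 0.3),
        M=rng.uniform(70.0, 95.0),
    )


@pytest.fixture
def late_params() -> CoDeParams:
    return preset("late")


@pytest.fixture
def early_params() -> CoDeParams:
    return preset("early")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
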