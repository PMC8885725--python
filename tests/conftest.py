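import numpy as np
import pytest

from vesikin import RateParams, build_scheme
from vesikin.config import load_preset


@pytest.fixture(scope="session")
def frog4():
    return load_preset("frog4").scheme()


@pytest.fixture(scope="session")
def cat4():
    return load_preset("cat4").scheme()


@pytest.fixture(scope="session")
def frog_params():
    return load_preset("frog4").rate_params()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
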