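import numpy as np
import pytest

from ermodel.params import default_binding_constants, default_params, default_rates


@pytest.fixture(scope="session")
def K():
    """Published binding constants (dependent ones derived)."""
    return default_binding_constants()


@pytest.fixture(scope="session")
def rates():
    return default_rates()


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
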