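import numpy as np
import pytest

from catpop import popcode as pc
from catpop.network import NetworkParams


@pytest.fixture(scope="session")
def categories():
    """Default three equally spaced categories."""
    return pc.CategorySet.equally_spaced(3)


@pytest.fixture(scope="session")
def population():
    """Full-size default population (300 units)."""
    return pc.make_uniform_population()


@pytest.fixture(scope="session")
def small_population():
    """Small population for cheap exhaustive checks."""
    return pc.make_uniform_population(12)


@pytest.fixture(scope="session")
def default_params():
    """Categorization-task parameters (top-down on)."""
    return NetworkParams()


@pytest.fixture(scope="session")
def feedforward_params():
    """No lateral feedback, no top-down: pure encoding."""
    return NetworkParams(lambda_hue=0.0, lambda_cat=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
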