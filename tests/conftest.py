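import numpy as np
import pytest

from ptmgeo.fixtures import THETA_FIXTURES
from ptmgeo.model import ConservedTotals, NondimensionalParameters, build_system


@pytest.fixture(scope="session")
def theta1_system_sigma10():
    params = NondimensionalParameters.from_theta(THETA_FIXTURES[1])
    return build_system(params, ConservedTotals.equal_enzymes(10.0))


@pytest.fixture(scope="session")
def random_parameter_draws():
    """Shared table of 200 ILR-like parameter draws in the unit box."""
    rng = np.random.default_rng(20241)
    return 10.0 ** rng.uniform(-1, 1, size=(200, 8))
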