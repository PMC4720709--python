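import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sdebayes as sb

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ou():
    """Class-0 trait-evolution model: beta=0.1, theta=80, sigma=1, xa=1."""
    return sb.ou_spec(0.1, 80.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def ou_grid():
    return sb.ObservationGrid(np.arange(1.0, 31.0), 1)


@pytest.fixture(scope="session")
def ou_grid_small():
    return sb.ObservationGrid(np.array([1.0, 2.0, 3.0]), 1)


@pytest.fixture(scope="session")
def eq33():
    """Ground-truth spec pair and grid of the p=3 benchmark."""
    from sdebayes.datasets import make_fixture

    return make_fixture("eq33")
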