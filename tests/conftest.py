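import numpy as np
import pytest

from il27sim.model import baseline_parameters
from il27sim.solver import build_grid


@pytest.fixture(scope="session")
def params():
    """Baseline transfected-tumor parameters (moderate IL-27 production)."""
    return baseline_parameters(mu1_case="moderate")


@pytest.fixture(scope="session")
def wildtype():
    return baseline_parameters("wildtype")


@pytest.fixture(scope="session")
def grid():
    """Coarse grid for fast solver tests."""
    return build_grid(0.5, 60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
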