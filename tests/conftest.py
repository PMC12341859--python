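import numpy as np
import pytest

from timesel.hmm import build_grid
from timesel.wf_core import PopParams


@pytest.fixture(scope="session")
def grid500():
    return build_grid(500)


@pytest.fixture(scope="session")
def grid499():
    # spacing 1/500, so frequencies like 0.25, 0.3, 0.5 sit exactly on grid
    return build_grid(499)


@pytest.fixture(scope="session")
def small_pop():
    return PopParams(Ne=100, u01=1e-6, u10=1e-6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
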