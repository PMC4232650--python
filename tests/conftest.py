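import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from retinoquant import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One moderate-load phantom shared by read-only tests."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def ma15_phantom():
    """Phantom with exactly 15 planted microaneurysms."""
    return make_phantom(PhantomSpec(seed=3, n_mas=15))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
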