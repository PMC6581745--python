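import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from mapboot import synthetic_data as sd
from mapboot.scheme_io import AcquisitionScheme


@pytest.fixture(scope="session")
def sparcgold():
    return sd.preset_scheme("sparcgold", seed=1)


@pytest.fixture(scope="session")
def sparc30():
    return sd.preset_scheme("sparc30", seed=1)


@pytest.fixture(scope="session")
def single_fiber_tensor():
    return np.diag(sd.DEFAULT_EIGENVALUES)


@pytest.fixture(scope="session")
def small_scheme():
    """A compact 3-shell scheme for cheap fitting tests."""
    return sd.preset_scheme("sparc20", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_scheme(bvals, bvecs, delta_small=0.062, delta_big=0.062):
    return AcquisitionScheme(np.asarray(bvals, float), np.asarray(bvecs, float), delta_small, delta_big)
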