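import numpy as np
import pytest

from cystir import synth
from cystir.spectra import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return synth.default_component_library()


@pytest.fixture(scope="session")
def refs(library, grid):
    return synth.reference_set_from_library(library, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
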