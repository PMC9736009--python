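import numpy as np
import pytest

from honeyspec import WavelengthGrid, generate_endmembers

MATERIALS = ["Q", "GS", "F", "G", "M"]


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def library(grid):
    """Two honeys and three syrups, drawn once per session."""
    return generate_endmembers(MATERIALS, grid, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
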