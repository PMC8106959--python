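import numpy as np
import pytest

from capscreen import generate_embryo, measure_embryo_axons, DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def chodl_embryo():
    """One rendered chodl-mutant embryo with its ground truth (seed 7)."""
    image, truth = generate_embryo("chodl-DMSO", 7)
    return image, truth


@pytest.fixture(scope="session")
def chodl_traces(chodl_embryo):
    image, truth = chodl_embryo
    return measure_embryo_axons(image[0], truth.geometry)


def blank_channel(geometry, value=0.0):
    return np.full(geometry.shape, value, dtype=np.float32)


@pytest.fixture
def straight_axon_channel(geometry):
    """A single bright, perfectly vertical 51-pixel axon; background zero."""
    chan = blank_channel(geometry)
    col = geometry.exit_cols[3]
    r0 = geometry.exit_row
    chan[r0:r0 + 51, col] = 150.0
    return chan, col
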