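import numpy as np
import pytest

from molfc.grid import VolumeGrid
from molfc.templates import MolecularTemplate


@pytest.fixture
def grid12():
    return VolumeGrid((12, 12, 12))


@pytest.fixture
def grid16():
    return VolumeGrid((16, 16, 16))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def template_from_array(data, grid, name="sys", mask=None):
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return MolecularTemplate(
        system_name=name, data=data, valid_mask=mask, grid=grid
    )


@pytest.fixture
def make_template():
    return template_from_array
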