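import numpy as np
import pytest

from pocketpharm.model import generate_pharmacophore
from pocketpharm.pocket import ToyPocketSpec, make_toy_pocket


@pytest.fixture(scope="session")
def toy_pocket():
    """Full five-environment synthetic pocket (structure, grid, truth)."""
    return make_toy_pocket(ToyPocketSpec(seed=1))


@pytest.fixture(scope="session")
def toy_model(toy_pocket):
    structure, grid, _ = toy_pocket
    return generate_pharmacophore(structure, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
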