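import numpy as np
import pytest

from scalepat.lattice import PatternState, build_hex_lattice, build_ring_lattice
from scalepat.rd import RDParams


@pytest.fixture(scope="session")
def hex66():
    """6x6 hexagonal patch, edge length 2 (Turing-unstable regime)."""
    return build_hex_lattice(6, 6, 2.0)


@pytest.fixture(scope="session")
def hex1010():
    return build_hex_lattice(10, 10, 2.0)


@pytest.fixture(scope="session")
def ring10():
    return build_ring_lattice(10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    return RDParams()


def random_pattern(lattice, seed=0, p_green=0.5):
    r = np.random.default_rng(seed)
    return PatternState((r.random(lattice.n_scales) < p_green).astype(np.int8))
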