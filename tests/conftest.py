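import numpy as np
import pytest

from pocketseg.synthetic import ToyComplexSpec, make_grid_pair, make_toy_complex


def pdb_line(serial, name, res, chain, seq, x, y, z, element, het=False):
    """Format one fixed-column PDB ATOM/HETATM record."""
    rec = "HETATM" if het else "ATOM  "
    return (
        f"{rec}{serial:5d} {name:<4s} {res:>3s} {chain}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(seed=7))


@pytest.fixture(scope="session")
def grid_pair():
    return make_grid_pair(seed=5, side=16)
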