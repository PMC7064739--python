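import numpy as np
import pytest

from jaggr import Box, MoleculeRecord


@pytest.fixture
def box100():
    return Box(100.0, 100.0, 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_molecule(rng, n_atoms=10, scale=5.0, molecule_id=0):
    """A random (generally non-degenerate) molecule for oracle tests."""
    positions = rng.normal(size=(n_atoms, 3)) * np.array([scale, 1.0, 0.3])
    masses = rng.uniform(1.0, 16.0, n_atoms)
    return MoleculeRecord(molecule_id=molecule_id, positions=positions,
                          masses=masses)
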