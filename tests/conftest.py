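import numpy as np
import pytest

from lassofold.fixtures import make_toy_native
from lassofold.forcefield import GoParameters
from lassofold.structure_io import NativeTopology


@pytest.fixture(scope="session")
def hairpin():
    return make_toy_native(12, "hairpin")


@pytest.fixture(scope="session")
def helix():
    return make_toy_native(15, "helix")


@pytest.fixture(scope="session")
def lasso():
    return make_toy_native(30, "lasso")


@pytest.fixture(scope="session")
def go_params():
    return GoParameters()


@pytest.fixture(scope="session")
def free_bead_topology():
    """A single unbonded bead: V = 0 identically."""
    return NativeTopology(
        n_residues=1, ca_coords=np.zeros((1, 3)), residue_labels=["A1"],
        bond_lengths_r0=np.empty(0), angles_theta0=np.empty(0),
        dihedrals_phi0=np.empty(0), contacts=[])


@pytest.fixture(scope="session")
def harmonic_chain_topology():
    """Three collinear beads: two stiff bonds + one angle, no contacts."""
    return NativeTopology(
        n_residues=3,
        ca_coords=np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]]),
        residue_labels=["A1", "A2", "A3"],
        bond_lengths_r0=np.array([3.8, 3.8]),
        angles_theta0=np.array([np.pi]),
        dihedrals_phi0=np.empty(0), contacts=[])


def random_coil(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random walk with ~3.8 Å steps, mildly self-avoiding by construction."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.vstack([np.zeros(3), np.cumsum(3.8 * steps, axis=0)])
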