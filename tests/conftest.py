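import numpy as np
import pytest

from accommodate.forcefield import Topology, build_bonded_terms
from accommodate.structures import Structure
from accommodate.synthetic_systems import make_two_state_arm, two_state_topology


def make_chain(n, spacing=3.8, jitter=0.0, seed=0, names=None):
    """A bonded bead chain along x with optional seeded jitter."""
    rng = np.random.default_rng(seed)
    coord = np.zeros((n, 3))
    coord[:, 0] = np.arange(n) * spacing
    if jitter:
        coord = coord + rng.normal(0, jitter, coord.shape)
    names = names or ["C1"] * n
    structure = Structure(["A"] * n, np.arange(1, n + 1), ["BEA"] * n,
                          names, ["C"] * n, coord)
    connectivity = [(i, i + 1) for i in range(n - 1)]
    return structure, connectivity


def single_bond_topology(r0=3.8, eps_bond=50.0):
    """Two atoms, one harmonic bond (the equipartition test system)."""
    structure, conn = make_chain(2, spacing=r0)
    bonded = build_bonded_terms(structure, conn, eps_bond=eps_bond)
    return Topology(n_atoms=2, bonded=bonded, contacts=[]), structure


@pytest.fixture(scope="session")
def arm_system():
    return make_two_state_arm(n_arm_beads=8, d_A=57.0, d_B=32.0, gate=True, seed=1)


@pytest.fixture(scope="session")
def arm_system_nogate():
    return make_two_state_arm(n_arm_beads=8, d_A=57.0, d_B=32.0, gate=False, seed=1)


@pytest.fixture(scope="session")
def arm_topology_v1(arm_system):
    return two_state_topology(arm_system, weight_AA=0.13)


@pytest.fixture(scope="session")
def arm_topology_v2(arm_system):
    return two_state_topology(arm_system, weight_AA=0.4, flavor="v2_gaussian")
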