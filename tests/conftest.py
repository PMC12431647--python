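import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wallfold import rna_model
from wallfold.forcefield import ForceFieldParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def system():
    return rna_model.default_system()


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def topology(system, params):
    return params.topology(system)


@pytest.fixture(scope="session")
def native(system):
    return rna_model.build_native_structure(system)


@pytest.fixture(scope="session")
def extended(system):
    return rna_model.build_extended_chain(system)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dimer_topology():
    """Two beads joined by one harmonic bond; no other terms."""
    empty2 = np.empty((0, 2), dtype=np.intp)
    return rna_model.Topology(
        masses=np.array([95.0, 100.0]),
        bond_idx=np.array([[0, 1]], dtype=np.intp),
        bond_r0=np.array([3.8]),
        bond_k=np.array([20.0]),
        angle_idx=np.empty((0, 3), dtype=np.intp),
        angle_th0=np.empty(0),
        angle_k=np.empty(0),
        dihedral_idx=np.empty((0, 4), dtype=np.intp),
        dihedral_phi0=np.empty(0),
        dihedral_k=np.empty(0),
        contact_idx=empty2,
        contact_r0=np.empty(0),
        contact_eps=np.empty(0),
        contact_kind=np.empty(0, dtype=np.intp),
        ev_pairs=empty2,
        bead_residue=np.array([1, 2], dtype=np.intp),
    )
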