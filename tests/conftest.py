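import numpy as np
import pytest

from chlorosim.geometry import (
    LatticeSpec,
    assign_donor_labels,
    build_tube,
    truncate_subsystem,
)
from chlorosim.hamiltonian import HamiltonianTrajectory


@pytest.fixture(scope="session")
def lattice() -> LatticeSpec:
    return LatticeSpec()


@pytest.fixture(scope="session")
def small_tube(lattice):
    """~120-site tube with donor labels, cheap enough for most tests."""
    tube = build_tube(lattice, 2.0, 6.0)
    return assign_donor_labels(tube, 0.7, seed=3)


@pytest.fixture(scope="session")
def middle_subsystem(lattice):
    """The spectroscopy subsystem: middle tube truncated to 35 nm."""
    tube = build_tube(lattice, 7.3, 40.0, tube_id=1)
    sub = truncate_subsystem(tube, 1, 35.0)
    return assign_donor_labels(sub, 0.7, seed=1)


def static_hamiltonian(eps, J, dipole_vectors, frames=200, dt=4.0) -> HamiltonianTrajectory:
    """Frozen Hamiltonian trajectory for closed-form spectra tests."""
    eps = np.asarray(eps, float)
    return HamiltonianTrajectory(
        diagonal=np.tile(eps, (frames, 1)),
        couplings=np.asarray(J, float),
        dipole_vectors=np.tile(np.asarray(dipole_vectors, float), (frames, 1, 1)),
        frame_dt=dt,
    )
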