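"""Exciton-state statistics of one disordered subsystem snapshot.

Diagonalizes a calibrated 2639-site Hamiltonian frame and tabulates per
state: energy, participation number (IPR), donor character, transition
dipole ratio and oscillator strength.  Prints the delocalization headline
numbers (super-radiant states, mid-band IPR maximum, donor-character trend).
"""

from pathlib import Path

import numpy as np

from chlorosim.analysis import (
    binned_profile,
    diagonalize,
    donor_character,
    ipr,
    oscillator_strengths,
    superradiance_histogram,
)
from chlorosim.disorder import DisorderSpec, emit_trajectory
from chlorosim.geometry import LatticeSpec, assign_donor_labels, build_tube, truncate_subsystem
from chlorosim.hamiltonian import assemble

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lattice = LatticeSpec()
    sub = assign_donor_labels(
        truncate_subsystem(build_tube(lattice, 7.3, 40.0, tube_id=1), 1, 35.0),
        0.7, seed=SEED,
    )
    traj = emit_trajectory(sub, DisorderSpec(seed=SEED, n_frames=1), 1)
    H = assemble(traj, sub)
    states = diagonalize(H.hamiltonian_frame(0), H.dipole_vectors[0])

    p = ipr(states)
    psi_d = donor_character(states, sub.donor.astype(float))
    f = oscillator_strengths(states)
    ratio = np.linalg.norm(states.state_dipoles, axis=1) / sub.dipole_mag

    sr = superradiance_histogram(states, sub.dipole_mag)
    print(f"{sub.n} states; band {states.energies.min():.0f} .. {states.energies.max():.0f} cm^-1")
    print(f"super-radiant states (ratio > 10): {len(sr['superradiant'])}, "
          f"max ratio {sr['max_ratio']:.1f} (implies ~{sr['max_ratio']**2:.0f} coherent molecules)")
    order = np.argsort(states.energies)
    dec = int(0.1 * states.n)
    print(f"lowest-decile states carry {f[order[:dec]].sum() / f.sum():.0%} of the oscillator strength")

    centers, means, counts = binned_profile(states.energies, p, 50.0)
    k = np.nanargmax(means)
    print(f"IPR maximal near {centers[k]:.0f} cm^-1 (participation ~{means[k]:.0f} molecules)")

    table = np.column_stack([np.arange(states.n), states.energies, p, psi_d, ratio, f])
    np.savetxt(
        RESULTS / "exciton_states.tsv", table,
        header="state energy_cm1 participation donor_character dipole_ratio oscillator_strength_D2",
    )
    print(f"wrote {RESULTS / 'exciton_states.tsv'}")


if __name__ == "__main__":
    main()
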