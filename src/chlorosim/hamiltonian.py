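"""Frenkel exciton Hamiltonian assembly.

The single-excitation Hamiltonian in the site basis is

    H(t) = sum_n [omega0 + dOmega_n(t)] B_n^+ B_n + sum_{m != n} J_mn(t) B_m^+ B_n

with the diagonal carrying the monomer Qy energy plus the environmental shift
and the couplings evaluated in the point-dipole approximation between Mg-atom
centres, without dielectric screening.  Site-energy shifts may alternatively
be evaluated from ground/excited-state partial charges via the intermolecular
Coulomb sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import COULOMB_CM_ANG, DIPOLE_CM_ANG3, NM_TO_ANG, OMEGA0_CM
from .geometry import SiteGeometry, SiteSet

__all__ = [
    "ChargeSet",
    "HamiltonianTrajectory",
    "coulomb_shift",
    "dipole_coupling",
    "coupling_matrix",
    "coupling_strength",
    "assemble",
    "PairGeometry",
]


@dataclass
class ChargeSet:
    """Per-atom partial charges of one molecule in ground and excited state."""

    labels: list[str]
    ground: np.ndarray   # (M,) e
    excited: np.ndarray  # (M,) e

    def __post_init__(self) -> None:
        self.ground = np.asarray(self.ground, float)
        self.excited = np.asarray(self.excited, float)
        for name, q in (("ground", self.ground), ("excited", self.excited)):
            if abs(q.sum()) > 1e-6:
                raise ValueError(
                    f"{name}-state charges must sum to the net molecular charge 0 "
                    f"within 1e-6 e (got {q.sum():.2e})"
                )


@dataclass
class HamiltonianTrajectory:
    """Time series of site energies, couplings and dipole vectors.

    ``couplings`` is a single symmetric (N, N) matrix shared by all frames
    (frozen geometry), a (frames, N, N) stack, or ``None`` for lazy mode in
    which per-frame matrices are rebuilt on demand from ``pair_geometry``
    and the instantaneous dipoles (the memory contract for long wobbling
    trajectories).  ``dipole_vectors`` carry magnitudes in Debye.
    """

    diagonal: np.ndarray        # (frames, N) cm^-1, absolute energies
    couplings: np.ndarray | None  # (N, N), (frames, N, N) cm^-1, or None
    dipole_vectors: np.ndarray  # (frames, N, 3) Debye
    frame_dt: float             # fs
    omega0: float = OMEGA0_CM
    dipole_mag: float = 1.0     # Debye, used in lazy mode
    pair_geometry: "PairGeometry | None" = None
    _cache: tuple | None = None

    @property
    def n_frames(self) -> int:
        return int(self.diagonal.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.diagonal.shape[1])

    def coupling_frame(self, k: int) -> np.ndarray:
        if self.couplings is not None:
            return self.couplings if self.couplings.ndim == 2 else self.couplings[k]
        if self.pair_geometry is None:
            raise ValueError("lazy Hamiltonian needs pair_geometry")
        if self._cache is not None and self._cache[0] == k:
            return self._cache[1]
        dirs = self.dipole_vectors[k] / self.dipole_mag
        J = self.pair_geometry.couplings(dirs, self.dipole_mag)
        self._cache = (k, J)
        return J

    def hamiltonian_frame(self, k: int) -> np.ndarray:
        H = np.array(self.coupling_frame(k), dtype=float, copy=True)
        H[np.diag_indices_from(H)] = self.diagonal[k]
        return H


def coulomb_shift(
    molecule_coords: np.ndarray,
    environment_coords: np.ndarray,
    charges: ChargeSet,
    environment_charges: np.ndarray | None = None,
    cutoff: float = 20.0,
    molecule_center: np.ndarray | None = None,
    environment_centers: np.ndarray | None = None,
) -> float:
    """Site-energy shift from the intermolecular Coulomb sum (cm^-1).

    ``sum_m sum_l (q_m^e - q_m^g) q_l^g / R_ml`` scaled by e^2/(4 pi eps0)
    in (cm^-1, Å, e) units.  ``environment_coords`` is (n_env, M_env, 3);
    environment molecules whose centre lies beyond ``cutoff`` (Å, Mg-Mg
    proxy) of the molecule centre contribute zero.
    """
    mol = np.asarray(molecule_coords, float)
    env = np.asarray(environment_coords, float)
    if env.ndim == 2:
        env = env[None]
    if environment_charges is None:
        environment_charges = np.tile(charges.ground, (env.shape[0], 1))
    environment_charges = np.asarray(environment_charges, float)
    dq = charges.excited - charges.ground

    if molecule_center is None:
        molecule_center = mol.mean(axis=0)
    if environment_centers is None:
        environment_centers = env.mean(axis=1)

    shift = 0.0
    for k in range(env.shape[0]):
        if np.linalg.norm(environment_centers[k] - molecule_center) > cutoff:
            continue
        R = np.linalg.norm(mol[:, None, :] - env[k][None, :, :], axis=2)
        if (R < 0.5).any():
            m, l = np.unravel_index(np.argmin(R), R.shape)
            raise ValueError(
                f"overlapping atoms: molecule atom {m} and environment atom {l} "
                f"of molecule {k} at R = {R[m, l]:.3f} Å (< 0.5 Å)"
            )
        shift += float(dq @ (environment_charges[k] / R.T).sum(axis=0))
    return COULOMB_CM_ANG * shift


def dipole_coupling(site_m: SiteGeometry, site_n: SiteGeometry) -> float:
    """Point-dipole excitonic coupling between two sites (cm^-1)."""
    rvec = (np.asarray(site_n.position) - np.asarray(site_m.position)) * NM_TO_ANG
    R = float(np.linalg.norm(rvec))
    if R == 0.0:
        raise ValueError("zero separation between sites")
    rhat = rvec / R
    dm = np.asarray(site_m.dipole_dir)
    dn = np.asarray(site_n.dipole_dir)
    kappa = float(dm @ dn - 3.0 * (dm @ rhat) * (dn @ rhat))
    return DIPOLE_CM_ANG3 * site_m.dipole_mag * site_n.dipole_mag * kappa / R**3


class PairGeometry:
    """Precomputed pair separations for fast per-frame coupling rebuilds.

    Holds 1/R^3 and the unit separation vectors for all site pairs (float32;
    ~130 MB for 2639 sites), so that per-frame coupling matrices under
    dipole wobble reduce to a handful of vectorized N x N operations.
    """

    def __init__(self, positions_nm: np.ndarray, cutoff: float | None = None):
        pos = np.asarray(positions_nm, np.float64) * NM_TO_ANG
        n = len(pos)
        diff = pos[None, :, :] - pos[:, None, :]          # (N, N, 3) m -> n
        R = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(R, np.inf)
        self.inv_r3 = np.asarray(R**-3, np.float32)
        if cutoff is not None:
            self.inv_r3[R > cutoff] = 0.0
        with np.errstate(invalid="ignore"):
            rhat = diff / R[:, :, None]
        rhat[np.isnan(rhat)] = 0.0
        self.rhat = np.asarray(rhat, np.float32)          # (N, N, 3)
        self.n = n

    def couplings(self, dipole_dirs: np.ndarray, dipole_mag: float) -> np.ndarray:
        """Symmetric coupling matrix (cm^-1, float32) for given unit dipoles."""
        d = np.asarray(dipole_dirs, np.float32)
        dot = d @ d.T
        proj_m = np.einsum("ik,ijk->ij", d, self.rhat)    # mu_m . rhat
        proj_n = np.einsum("jk,ijk->ij", d, self.rhat)    # mu_n . rhat
        kappa = dot - 3.0 * proj_m * proj_n
        J = np.float32(DIPOLE_CM_ANG3 * dipole_mag**2) * kappa * self.inv_r3
        np.fill_diagonal(J, 0.0)
        return J


def coupling_matrix(sites: SiteSet, cutoff: float | None = None) -> np.ndarray:
    """All-pairs point-dipole coupling matrix for a static geometry (cm^-1)."""
    pg = PairGeometry(sites.positions, cutoff=cutoff)
    return pg.couplings(sites.dipole_dirs, sites.dipole_mag)


def coupling_strength(couplings: np.ndarray, site_n: int | None = None) -> np.ndarray | float:
    """Signed sum of all pairwise couplings involving each molecule.

    ``S_n(t) = sum_{m != n} J_nm(t)``; a single fluctuating number per
    molecule whose negative ensemble mean marks J-aggregate behaviour.
    """
    S = np.asarray(couplings, float).sum(axis=-1)
    if site_n is None:
        return S
    return float(S[..., site_n])


def assemble(
    trajectory,
    geometry: SiteSet,
    mode: Literal["direct-energies", "charge-based"] = "direct-energies",
    charge_evaluator=None,
    coupling_cutoff: float | None = None,
    omega0: float = OMEGA0_CM,
    store: Literal["auto", "dense", "lazy"] = "auto",
) -> HamiltonianTrajectory:
    """Build the time-dependent Hamiltonian from geometry plus a trajectory.

    ``trajectory`` is a ``SiteTrajectory`` (energies as shifts dOmega_n(t),
    unit dipole directions per frame).  The diagonal becomes
    ``omega0 + dOmega_n(t)``; couplings are recomputed per frame from the
    instantaneous dipole vectors whenever the dipoles move, otherwise a
    single matrix is shared across frames.
    """
    energies = np.asarray(trajectory.energies, float)
    dipoles = np.asarray(trajectory.dipoles, np.float32)
    n_frames, n = energies.shape
    if n != geometry.n or dipoles.shape[1] != geometry.n:
        raise ValueError(
            f"trajectory covers {n} sites but geometry has {geometry.n}"
        )

    if mode == "charge-based":
        if charge_evaluator is None:
            raise ValueError("charge-based mode requires a charge_evaluator(frame_index) -> shifts")
        energies = np.stack([np.asarray(charge_evaluator(k), float) for k in range(n_frames)])

    positions = geometry.positions
    if getattr(trajectory, "positions", None) is not None:
        positions = trajectory.positions
    pg = PairGeometry(positions, cutoff=coupling_cutoff)
    wobbling = n_frames > 1 and not np.allclose(dipoles[0], dipoles[-1])
    if store == "auto":
        store = "dense" if (not wobbling or n_frames * n * n <= int(2e8)) else "lazy"
    if not wobbling:
        couplings = pg.couplings(dipoles[0], geometry.dipole_mag)
    elif store == "dense":
        couplings = np.stack([pg.couplings(dipoles[k], geometry.dipole_mag) for k in range(n_frames)])
    else:
        couplings = None

    mu_vectors = dipoles * np.float32(geometry.dipole_mag)
    return HamiltonianTrajectory(
        diagonal=omega0 + energies,
        couplings=couplings,
        dipole_vectors=mu_vectors,
        frame_dt=float(trajectory.frame_dt),
        omega0=omega0,
        dipole_mag=geometry.dipole_mag,
        pair_geometry=pg if couplings is None else None,
    )
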