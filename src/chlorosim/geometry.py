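"""Tubular syn/anti lattice construction for chlorosome-like BChl c aggregates.

The aggregate is modelled as concentric cylinders obtained by rolling an
oblique two-dimensional lattice (two molecules per unit cell, one *syn* and
one *anti*) onto cylinders of prescribed radii.  Positions are Mg-atom
proxies; each site carries a unit transition-dipole direction lying in the
(rolled) sheet plane.

Coordinate convention: tube axis = z, right-handed frame, lengths in nm.

Because the circumference 2*pi*R is generally not a lattice translation, the
wrap vector is snapped to the nearest integer lattice vector compatible with
the chiral angle and the effective radius is rescaled accordingly (the seam
then closes exactly); the adjustment is reported through ``TubeWrap``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import DIPOLE_MAG_D

__all__ = [
    "LatticeSpec",
    "SiteGeometry",
    "SiteSet",
    "TubeWrap",
    "build_sheet",
    "roll_tube",
    "build_tube",
    "build_three_tube_system",
    "assign_donor_labels",
    "truncate_subsystem",
]

#: in-plane angle (deg, from the a lattice vector) of the N_A->N_C transition
#: dipole axis.  Calibrated so that the ensemble-mean coupling strength on the
#: ideal middle tube is ~ -1350 cm^-1 (see docs/methods.md).
DEFAULT_DIPOLE_ANGLE_DEG = -8.3


@dataclass(frozen=True)
class LatticeSpec:
    """Oblique lattice and rolling parameters of the tubular aggregate."""

    a: float = 1.48                # nm
    b: float = 0.98                # nm
    gamma: float = 124.3           # deg, angle between a and b
    delta: float = 49.6            # deg, chiral (rolling) angle
    radii: Sequence[float] = (5.2, 7.3, 9.5)   # nm
    length: float = 120.0          # nm
    dipole_angle: float = DEFAULT_DIPOLE_ANGLE_DEG  # deg, in-plane
    dipole_mag: float = DIPOLE_MAG_D               # Debye

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"lattice constant a must be > 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"lattice constant b must be > 0, got {self.b}")
        if not 0.0 < self.gamma < 180.0:
            raise ValueError(f"lattice angle gamma must lie in (0, 180) deg, got {self.gamma}")
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"all tube radii must be > 0, got {tuple(self.radii)}")
        if self.length < 0:
            raise ValueError(f"tube length must be >= 0, got {self.length}")

    @property
    def avec(self) -> np.ndarray:
        return np.array([self.a, 0.0])

    @property
    def bvec(self) -> np.ndarray:
        g = math.radians(self.gamma)
        return np.array([self.b * math.cos(g), self.b * math.sin(g)])

    @property
    def cell_area(self) -> float:
        av, bv = self.avec, self.bvec
        return abs(float(av[0] * bv[1] - av[1] * bv[0]))


class SiteGeometry(NamedTuple):
    """Per-molecule view: Mg position, dipole direction and class labels."""

    position: np.ndarray      # (3,) nm
    dipole_dir: np.ndarray    # (3,) unit vector
    dipole_mag: float         # Debye
    tube_id: int
    cell_index: tuple[int, int]
    conformer: str            # "syn" | "anti"
    donor: bool


@dataclass
class TubeWrap:
    """Integer wrap vector snapped to the requested radius/chiral angle."""

    p: int
    q: int
    circumference: float      # nm, |p a + q b|
    radius_requested: float   # nm
    radius_effective: float   # nm
    delta_requested: float    # deg
    delta_effective: float    # deg


@dataclass
class SiteSet:
    """Vectorized container for a collection of molecular sites."""

    positions: np.ndarray          # (N, 3) nm
    dipole_dirs: np.ndarray        # (N, 3) unit
    dipole_mag: float              # Debye
    tube_id: np.ndarray            # (N,) int
    cell_index: np.ndarray         # (N, 2) int
    is_anti: np.ndarray            # (N,) bool
    donor: np.ndarray              # (N,) bool
    lattice: LatticeSpec | None = None
    wraps: dict[int, TubeWrap] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    def __len__(self) -> int:
        return self.n

    @property
    def conformer(self) -> np.ndarray:
        return np.where(self.is_anti, "anti", "syn")

    def __iter__(self) -> Iterator[SiteGeometry]:
        for k in range(self.n):
            yield self[k]

    def __getitem__(self, k: int) -> SiteGeometry:
        return SiteGeometry(
            position=self.positions[k],
            dipole_dir=self.dipole_dirs[k],
            dipole_mag=self.dipole_mag,
            tube_id=int(self.tube_id[k]),
            cell_index=(int(self.cell_index[k, 0]), int(self.cell_index[k, 1])),
            conformer="anti" if self.is_anti[k] else "syn",
            donor=bool(self.donor[k]),
        )

    def subset(self, mask: np.ndarray) -> "SiteSet":
        return SiteSet(
            positions=self.positions[mask],
            dipole_dirs=self.dipole_dirs[mask],
            dipole_mag=self.dipole_mag,
            tube_id=self.tube_id[mask],
            cell_index=self.cell_index[mask],
            is_anti=self.is_anti[mask],
            donor=self.donor[mask],
            lattice=self.lattice,
            wraps=dict(self.wraps),
        )

    @staticmethod
    def concatenate(parts: Sequence["SiteSet"]) -> "SiteSet":
        wraps: dict[int, TubeWrap] = {}
        for p in parts:
            wraps.update(p.wraps)
        return SiteSet(
            positions=np.concatenate([p.positions for p in parts]),
            dipole_dirs=np.concatenate([p.dipole_dirs for p in parts]),
            dipole_mag=parts[0].dipole_mag,
            tube_id=np.concatenate([p.tube_id for p in parts]),
            cell_index=np.concatenate([p.cell_index for p in parts]),
            is_anti=np.concatenate([p.is_anti for p in parts]),
            donor=np.concatenate([p.donor for p in parts]),
            lattice=parts[0].lattice,
            wraps=wraps,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "mux": self.dipole_dirs[:, 0],
                "muy": self.dipole_dirs[:, 1],
                "muz": self.dipole_dirs[:, 2],
                "dipole_mag": self.dipole_mag,
                "tube": self.tube_id,
                "cell_i": self.cell_index[:, 0],
                "cell_j": self.cell_index[:, 1],
                "conformer": self.conformer,
                "donor": self.donor,
            }
        )


def build_sheet(spec: LatticeSpec, n_cells_a: int, n_cells_b: int) -> SiteSet:
    """Flat oblique sheet of ``n_cells_a x n_cells_b`` unit cells.

    Each cell carries a *syn* site at the cell origin and an *anti* site at
    half a cell diagonal, so that the rows along ``b`` are syn-anti
    alternating zigzag stacks; dipoles lie in the sheet plane at the
    configured in-plane angle.  Deterministic.
    """
    if n_cells_a < 0 or n_cells_b < 0:
        raise ValueError("cell counts must be >= 0")
    n_cells = n_cells_a * n_cells_b
    ii, jj = np.meshgrid(np.arange(n_cells_a), np.arange(n_cells_b), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    origins = ii[:, None] * spec.avec[None, :] + jj[:, None] * spec.bvec[None, :]
    # anti molecules sit half a cell along both lattice vectors: stacks along
    # b are syn-anti alternating zigzag chains (the aggregate's stacking motif)
    anti_offset = 0.5 * (spec.avec + spec.bvec)

    pos2 = np.concatenate([origins, origins + anti_offset[None, :]])
    cell_index = np.concatenate([np.stack([ii, jj], axis=1)] * 2) if n_cells else np.zeros((0, 2), int)
    is_anti = np.concatenate([np.zeros(n_cells, bool), np.ones(n_cells, bool)])

    alpha = math.radians(spec.dipole_angle)
    d2 = np.array([math.cos(alpha), math.sin(alpha)])
    positions = np.column_stack([pos2, np.zeros(len(pos2))])
    dipoles = np.tile(np.array([d2[0], d2[1], 0.0]), (len(pos2), 1))

    return SiteSet(
        positions=positions,
        dipole_dirs=dipoles,
        dipole_mag=spec.dipole_mag,
        tube_id=np.zeros(len(pos2), int),
        cell_index=cell_index.astype(int),
        is_anti=is_anti,
        donor=np.zeros(len(pos2), bool),
        lattice=spec,
    )


def _wrap_vector(spec: LatticeSpec, radius: float, delta: float) -> TubeWrap:
    """Integer lattice vector closest to circumference 2*pi*R at angle delta."""
    av, bv = spec.avec, spec.bvec
    target_len = 2.0 * math.pi * radius
    d = math.radians(delta)
    target = target_len * np.array([math.cos(d), math.sin(d)])
    # real-valued solution of p*a + q*b = target
    M = np.column_stack([av, bv])
    pq = np.linalg.solve(M, target)
    best = None
    for p in range(int(math.floor(pq[0])) - 2, int(math.ceil(pq[0])) + 3):
        for q in range(int(math.floor(pq[1])) - 2, int(math.ceil(pq[1])) + 3):
            if p == 0 and q == 0:
                continue
            C = p * av + q * bv
            clen = float(np.linalg.norm(C))
            ang = math.degrees(math.atan2(C[1], C[0]))
            score = ((clen - target_len) / target_len) ** 2 + math.radians(ang - delta) ** 2
            if best is None or score < best[0]:
                best = (score, p, q, clen, ang)
    _, p, q, clen, ang = best
    return TubeWrap(
        p=p,
        q=q,
        circumference=clen,
        radius_requested=radius,
        radius_effective=clen / (2.0 * math.pi),
        delta_requested=delta,
        delta_effective=ang,
    )


def roll_tube(
    sheet: SiteSet,
    radius: float,
    delta: float | None = None,
    length: float | None = None,
    tube_id: int = 0,
) -> SiteSet:
    """Roll a flat sheet onto a cylinder of (approximately) the given radius.

    The wrap direction is the integer lattice vector closest to circumference
    ``2*pi*radius`` at the chiral angle; the effective radius is rescaled so
    the seam closes exactly (reported via a warning and ``SiteSet.wraps``).
    Sites are kept for one full circumference and an axial window of the
    given length, centred at z = 0; dipole directions are co-rotated with the
    local surface frame.

    Raises ``ValueError`` if the sheet is too small to cover the cylinder.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    spec = sheet.lattice
    if spec is None:
        raise ValueError("sheet does not carry its LatticeSpec")
    if delta is None:
        delta = spec.delta
    if length is None:
        length = spec.length

    wrap = _wrap_vector(spec, radius, delta)
    if abs(wrap.radius_effective - radius) > 1e-9:
        warnings.warn(
            f"tube {tube_id}: seam quantization adjusted radius "
            f"{radius:.3f} -> {wrap.radius_effective:.3f} nm "
            f"(wrap vector p={wrap.p}, q={wrap.q})",
            stacklevel=2,
        )
    clen = wrap.circumference
    chat_ang = math.atan2(wrap.q * spec.bvec[1], wrap.p * spec.a + wrap.q * spec.bvec[0])
    chat = np.array([math.cos(chat_ang), math.sin(chat_ang)])
    that = np.array([-chat[1], chat[0]])  # axial direction (right-handed)

    pos2 = sheet.positions[:, :2]
    u = pos2 @ chat
    z = pos2 @ that

    eps = 1e-9
    # centre the axial window on the populated region of the sheet
    z0 = 0.5 * (z.min() + z.max()) - 0.5 * length
    keep = (u >= -eps) & (u < clen - eps) & (z >= z0 - eps) & (z < z0 + length - eps)
    n_kept = int(keep.sum())

    # geometric coverage check: the (u, z) window corners must map inside
    # the sheet's populated cell-index range
    M = np.column_stack([spec.avec, spec.bvec])
    corners_uz = np.array([[0.0, z0], [clen, z0], [0.0, z0 + length], [clen, z0 + length]])
    corners_xy = corners_uz[:, :1] * chat[None, :] + corners_uz[:, 1:] * that[None, :]
    ij = np.linalg.solve(M, corners_xy.T).T
    have_lo = sheet.cell_index.min(axis=0)
    have_hi = sheet.cell_index.max(axis=0)
    if length > 0 and (
        np.any(np.floor(ij.min(axis=0)) < have_lo - 1)
        or np.any(np.ceil(ij.max(axis=0)) > have_hi + 1)
    ):
        raise ValueError(
            f"sheet too small to cover cylinder: needs cells "
            f"i in [{np.floor(ij[:, 0].min()):.0f}, {np.ceil(ij[:, 0].max()):.0f}], "
            f"j in [{np.floor(ij[:, 1].min()):.0f}, {np.ceil(ij[:, 1].max()):.0f}] "
            f"for circumference {clen:.2f} nm x length {length:.2f} nm"
        )

    u = u[keep]
    zc = z[keep] - (z0 + 0.5 * length)   # centred axial coordinate
    theta = 2.0 * math.pi * u / clen
    R = wrap.radius_effective
    positions = np.column_stack([R * np.cos(theta), R * np.sin(theta), zc])

    d2 = sheet.dipole_dirs[keep, :2]
    du = d2 @ chat
    dz = d2 @ that
    theta_hat = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)])
    dipoles = du[:, None] * theta_hat
    dipoles[:, 2] += dz
    dipoles /= np.linalg.norm(dipoles, axis=1, keepdims=True)

    # seam sanity: no two Mg positions closer than 0.1 nm
    _check_min_separation(positions, 0.1)

    return SiteSet(
        positions=positions,
        dipole_dirs=dipoles,
        dipole_mag=sheet.dipole_mag,
        tube_id=np.full(n_kept, tube_id, int),
        cell_index=sheet.cell_index[keep],
        is_anti=sheet.is_anti[keep],
        donor=sheet.donor[keep],
        lattice=spec,
        wraps={tube_id: wrap},
    )


def _check_min_separation(positions: np.ndarray, min_sep: float) -> None:
    """Grid-based O(N) minimum-distance check (fails on overlapping sites)."""
    if len(positions) < 2:
        return
    cell = min_sep
    keys = np.floor(positions / cell).astype(np.int64)
    seen: dict[tuple[int, int, int], list[int]] = {}
    for idx, key in enumerate(map(tuple, keys)):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for other in seen.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = np.linalg.norm(positions[idx] - positions[other])
                        if d < min_sep:
                            raise ValueError(
                                f"sites {other} and {idx} closer than {min_sep} nm ({d:.4f} nm): seam overlap"
                            )
        seen.setdefault(tuple(key), []).append(idx)


def build_tube(
    spec: LatticeSpec,
    radius: float,
    length: float | None = None,
    tube_id: int = 0,
) -> SiteSet:
    """Build one tube directly, auto-sizing the flat sheet before rolling."""
    if length is None:
        length = spec.length
    wrap = _wrap_vector(spec, radius, spec.delta)
    clen = wrap.circumference
    # invert the (u, z) rectangle corners back to (i, j) cell ranges
    chat_ang = math.atan2(wrap.q * spec.bvec[1], wrap.p * spec.a + wrap.q * spec.bvec[0])
    chat = np.array([math.cos(chat_ang), math.sin(chat_ang)])
    that = np.array([-chat[1], chat[0]])
    M = np.column_stack([spec.avec, spec.bvec])
    corners_uz = np.array(
        [[0, 0], [clen, 0], [0, length], [clen, length]], dtype=float
    )
    corners_xy = corners_uz[:, :1] * chat[None, :] + corners_uz[:, 1:] * that[None, :]
    ij = np.linalg.solve(M, corners_xy.T).T
    i_lo, j_lo = np.floor(ij.min(axis=0)).astype(int) - 2
    i_hi, j_hi = np.ceil(ij.max(axis=0)).astype(int) + 2

    spec_local = spec
    na, nb = i_hi - i_lo + 1, j_hi - j_lo + 1
    sheet = build_sheet(spec_local, na, nb)
    # shift cell indices and positions to the computed window
    offset = i_lo * spec.avec + j_lo * spec.bvec
    sheet.positions[:, :2] += offset[None, :]
    sheet.cell_index[:, 0] += i_lo
    sheet.cell_index[:, 1] += j_lo
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tube = roll_tube(sheet, radius, spec.delta, length, tube_id=tube_id)
    return tube


def build_three_tube_system(spec: LatticeSpec) -> SiteSet:
    """Concentric multi-tube aggregate at the configured radii and length."""
    tubes = [build_tube(spec, r, spec.length, tube_id=k) for k, r in enumerate(spec.radii)]
    return SiteSet.concatenate(tubes)


def truncate_subsystem(sites: SiteSet, tube_id: int, length: float) -> SiteSet:
    """Centred axial window of the given length on one tube."""
    present = np.unique(sites.tube_id)
    if tube_id not in present:
        raise ValueError(f"unknown tube_id {tube_id}; present: {present.tolist()}")
    z = sites.positions[:, 2]
    built = z.max() - z.min() if sites.n else 0.0
    if length > built + 1e-6:
        raise ValueError(f"requested window {length} nm exceeds built length {built:.2f} nm")
    if length <= 0:
        return sites.subset(np.zeros(sites.n, bool))
    eps = 1e-9
    mask = (sites.tube_id == tube_id) & (z >= -length / 2 - eps) & (z < length / 2 + eps)
    return sites.subset(mask)


def assign_donor_labels(
    sites: SiteSet,
    donor_fraction: float = 0.7,
    seed: int = 0,
    mean_run: float = 7.0,
) -> SiteSet:
    """Seeded hydrogen-bond-donor labels, contiguous in runs along stacks.

    Donors form geometric hydrogen-bond chains, so labels are assigned in
    runs along each stack (sites sharing conformer and cell column, ordered
    by the second cell index).  Run lengths are geometric with mean
    ``mean_run`` for donors and ``mean_run*(1-f)/f`` for non-donors; after
    assignment, single labels at run boundaries are flipped so the global
    donor count matches ``round(donor_fraction*N)`` to within +-1.
    """
    if not 0.0 <= donor_fraction <= 1.0:
        raise ValueError(f"donor_fraction must lie in [0, 1], got {donor_fraction}")
    out = sites.subset(np.ones(sites.n, bool))
    donor = np.zeros(sites.n, bool)
    if sites.n == 0 or donor_fraction == 0.0:
        out.donor = donor
        return out
    if donor_fraction == 1.0:
        out.donor = np.ones(sites.n, bool)
        return out

    rng = np.random.default_rng(seed)
    f = donor_fraction
    run_d = max(mean_run, 1.0)
    run_n = max(run_d * (1.0 - f) / f, 1.0)

    # stacks: same tube, conformer and cell column; ordered along the stack
    key = (
        sites.tube_id.astype(np.int64) * 4_000_000
        + sites.is_anti.astype(np.int64) * 2_000_000
        + (sites.cell_index[:, 0] + 1_000_000)
    )
    order = np.lexsort((sites.cell_index[:, 1], key))
    for stack in np.split(order, np.nonzero(np.diff(key[order]))[0] + 1):
        pos = 0
        state = rng.random() < f
        while pos < len(stack):
            mean = run_d if state else run_n
            length = 1 + rng.geometric(1.0 / mean) - 1 if mean > 1 else 1
            length = max(int(length), 1)
            donor[stack[pos : pos + length]] = state
            pos += length
            state = not state

    # correct the global count to round(f*N) by flipping run-boundary sites
    target = int(round(f * sites.n))
    boundary = _run_boundary_sites(sites, donor, key, order)
    count = int(donor.sum())
    guard = 0
    while count != target and guard < sites.n:
        need_donor = count < target
        candidates = boundary[donor[boundary] != need_donor]
        if len(candidates) == 0:
            candidates = np.nonzero(donor != need_donor)[0]
        pick = candidates[rng.integers(len(candidates))]
        donor[pick] = need_donor
        count += 1 if need_donor else -1
        guard += 1

    out.donor = donor
    return out


def _run_boundary_sites(sites: SiteSet, donor: np.ndarray, key: np.ndarray, order: np.ndarray) -> np.ndarray:
    lab = donor[order]
    same_stack = np.diff(key[order]) == 0
    flips = np.nonzero((lab[1:] != lab[:-1]) & same_stack)[0]
    idx = np.unique(np.concatenate([flips, flips + 1]))
    return order[idx]
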