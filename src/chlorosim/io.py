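"""File-format adapters: site tables, trajectory containers, spectra, XYZ.

Plain-text formats carry a commented header with a format version, units
and provenance (seed, spec hash) so every output is self-describing; bulky
trajectory and Hamiltonian data use HDF5 containers with named datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .disorder import SiteTrajectory
from .geometry import LatticeSpec, SiteSet
from .spectra import SpectralCurve, TwoDSpectrum

__all__ = [
    "write_site_table",
    "read_site_table",
    "write_xyz",
    "write_trajectory",
    "read_trajectory",
    "write_spectrum",
    "read_spectrum",
    "write_twod",
    "read_twod",
    "read_atomistic_frames",
    "write_atomistic_frames",
    "expand_frames_hold",
]

_SITE_HEADER = "# chlorosim site table v1 | coords nm (tube axis = z) | dipole unit vectors | dipole_mag Debye"


def write_site_table(sites: SiteSet, path: str | Path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_SITE_HEADER + "\n")
        if metadata:
            fh.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
        sites.to_dataframe().to_csv(fh, index_label="index")


def read_site_table(path: str | Path, lattice: LatticeSpec | None = None) -> SiteSet:
    df = pd.read_csv(path, comment="#", index_col=0)
    return SiteSet(
        positions=df[["x", "y", "z"]].to_numpy(float),
        dipole_dirs=df[["mux", "muy", "muz"]].to_numpy(float),
        dipole_mag=float(df["dipole_mag"].iloc[0]),
        tube_id=df["tube"].to_numpy(int),
        cell_index=df[["cell_i", "cell_j"]].to_numpy(int),
        is_anti=(df["conformer"] == "anti").to_numpy(),
        donor=df["donor"].astype(bool).to_numpy(),
        lattice=lattice,
    )


def write_xyz(sites: SiteSet, path: str | Path, element: str = "Mg") -> None:
    """Mg-proxy positions as XYZ (Å) for visualization."""
    with open(path, "w") as fh:
        fh.write(f"{sites.n}\n")
        fh.write("chlorosim Mg proxies (converted nm -> Angstrom)\n")
        for p in sites.positions * 10.0:
            fh.write(f"{element} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def write_trajectory(traj: SiteTrajectory, sites: SiteSet, path: str | Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["format"] = "chlorosim-trajectory-v1"
        h5.attrs["frame_dt_fs"] = traj.frame_dt
        h5.attrs["metadata"] = json.dumps(traj.metadata, sort_keys=True)
        h5.create_dataset("energies", data=traj.energies, compression="gzip")
        h5.create_dataset("dipoles", data=np.asarray(traj.dipoles, np.float32), compression="gzip")
        if traj.positions is not None:
            h5.create_dataset("positions", data=traj.positions)
        h5.create_dataset("base_positions", data=sites.positions)
        h5.create_dataset("donor", data=sites.donor)
        h5.create_dataset("is_anti", data=sites.is_anti)
        h5.create_dataset("tube_id", data=sites.tube_id)


def read_trajectory(path: str | Path) -> tuple[SiteTrajectory, dict]:
    with h5py.File(path, "r") as h5:
        traj = SiteTrajectory(
            energies=h5["energies"][...],
            dipoles=h5["dipoles"][...].astype(float),
            frame_dt=float(h5.attrs["frame_dt_fs"]),
            positions=h5["positions"][...] if "positions" in h5 else None,
            metadata=json.loads(h5.attrs["metadata"]),
        )
        labels = {
            "donor": h5["donor"][...],
            "is_anti": h5["is_anti"][...],
            "tube_id": h5["tube_id"][...],
            "base_positions": h5["base_positions"][...],
        }
    return traj, labels


def write_spectrum(curve: SpectralCurve, path: str | Path) -> None:
    meta = json.dumps(curve.metadata, sort_keys=True, default=float)
    np.savetxt(
        path,
        np.column_stack([curve.frequency, curve.intensity]),
        header=f"chlorosim spectrum v1 | cm^-1, intensity (arb)\n{meta}",
    )


def read_spectrum(path: str | Path) -> SpectralCurve:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    for ln in lines[:4]:
        if ln.startswith("#") and "{" in ln:
            meta = json.loads(ln.lstrip("# ").strip())
    data = np.loadtxt(path)
    return SpectralCurve(data[:, 0], data[:, 1], metadata=meta)


def write_twod(spec: TwoDSpectrum, path: str | Path) -> None:
    """Matrix text: first row omega3 axis, first column omega1 axis."""
    meta = json.dumps(spec.metadata, sort_keys=True, default=float)
    with open(path, "w") as fh:
        fh.write("# chlorosim 2DES v1 | absorptive, bleach positive | axes cm^-1\n")
        fh.write("# " + meta + "\n")
        fh.write("omega1\\omega3 " + " ".join(f"{w:.3f}" for w in spec.omega3) + "\n")
        for i, w1 in enumerate(spec.omega1):
            fh.write(f"{w1:.3f} " + " ".join(f"{v:.6e}" for v in spec.amplitude[i]) + "\n")


def read_twod(path: str | Path) -> TwoDSpectrum:
    meta: dict = {}
    with open(path) as fh:
        lines = [ln for ln in fh.readlines() if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if "{" in ln:
                meta = json.loads(ln.lstrip("# ").strip())
            continue
        body.append(ln)
    omega3 = np.array([float(v) for v in body[0].split()[1:]])
    omega1 = []
    rows = []
    for ln in body[1:]:
        parts = ln.split()
        omega1.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    return TwoDSpectrum(np.array(omega1), omega3, np.array(rows), metadata=meta)


def read_atomistic_frames(path: str | Path) -> tuple[list[np.ndarray], list[list[str]], dict]:
    """Multi-frame XYZ reader (coordinates per frame, element labels).

    Frame spacing, if present as ``dt=<fs>`` in a comment line, is returned
    in the metadata.  Malformed frames raise with the offending line number.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    labels: list[list[str]] = []
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n_atoms = int(lines[k].split()[0])
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{k + 1}: expected atom count, got {lines[k]!r}")
        comment = lines[k + 1] if k + 1 < len(lines) else ""
        for token in comment.split():
            if token.startswith("dt="):
                meta["frame_dt_fs"] = float(token[3:])
        coords = np.empty((n_atoms, 3))
        elems = []
        for a in range(n_atoms):
            ln_no = k + 2 + a
            if ln_no >= len(lines):
                raise ValueError(f"{path}:{ln_no + 1}: truncated frame ({a}/{n_atoms} atoms)")
            parts = lines[ln_no].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln_no + 1}: malformed atom line {lines[ln_no]!r}")
            elems.append(parts[0])
            try:
                coords[a] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ValueError(f"{path}:{ln_no + 1}: non-numeric coordinate in {lines[ln_no]!r}")
        frames.append(coords)
        labels.append(elems)
        k += 2 + n_atoms
    return frames, labels, meta


def write_atomistic_frames(
    frames: list[np.ndarray],
    labels: list[list[str]],
    path: str | Path,
    frame_dt: float | None = None,
) -> None:
    with open(path, "w") as fh:
        for coords, elems in zip(frames, labels):
            fh.write(f"{len(elems)}\n")
            fh.write(f"chlorosim frame dt={frame_dt}\n" if frame_dt else "chlorosim frame\n")
            for e, p in zip(elems, coords):
                fh.write(f"{e} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def expand_frames_hold(frames: list[np.ndarray], factor: int) -> list[np.ndarray]:
    """Hold-constant expansion of coarse frames onto a finer time grid.

    Each stored frame is repeated ``factor`` times (e.g. 20 fs MD frames
    consumed at a 4 fs propagation step give factor 5).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return [frame for frame in frames for _ in range(factor)]
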