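"""Wavefunction propagation under the time-dependent exciton Hamiltonian.

Within each trajectory frame the Hamiltonian is held constant and the
wavefunction advanced with the exact unitary ``exp(-i H dt / hbar)``;
longer intervals are time-ordered products of these per-frame propagators.
Small systems use an eigendecomposition of the frame Hamiltonian, large
ones a matrix-free Lanczos (Krylov) exponential; both are unitary to
tight tolerance.

The doubly-excited manifold uses hard-core pair states |ij> (i<j, no
double occupation of a site).  A two-exciton amplitude is stored as a
symmetric N x N matrix C with zero diagonal; the Hamiltonian action is then

    (H2 C)_ij = (eps_i + eps_j) C_ij + (J C + C J)_ij,   diagonal zeroed,

which is algebraically identical to the pair-basis matrix and keeps the
cost at two dense matrix products per application.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .constants import TWO_PI_C

__all__ = [
    "Propagator",
    "TwoExcitonBasis",
    "step_one_exciton",
    "propagate_interval",
    "build_two_exciton_hamiltonian",
    "pair_matrix_from_vector",
    "pair_vector_from_matrix",
    "create_double",
    "annihilate_double",
    "two_exciton_apply",
    "step_two_exciton",
]

_HERMITICITY_TOL = 1e-8


@dataclass
class Propagator:
    """Per-frame unitary evolution settings."""

    step: float = 4.0          # fs
    method: str = "auto"       # "eigh" | "lanczos" | "auto"
    lanczos_tol: float = 1e-10
    lanczos_max: int = 60
    eigh_threshold: int = 600  # use eigendecomposition below this N

    def choose(self, n: int) -> str:
        if self.method != "auto":
            return self.method
        return "eigh" if n <= self.eigh_threshold else "lanczos"


def _check_hermitian(H: np.ndarray) -> None:
    if not np.allclose(H, H.T.conj(), atol=_HERMITICITY_TOL * max(1.0, np.abs(H).max())):
        raise ValueError("Hamiltonian frame is not Hermitian")


def step_one_exciton(
    H_frame: np.ndarray,
    psi: np.ndarray,
    dt: float,
    propagator: Propagator | None = None,
    check: bool = True,
) -> np.ndarray:
    """Advance ``psi`` (or a stack of column vectors) by one frozen-H step."""
    if propagator is None:
        propagator = Propagator()
    H = np.asarray(H_frame)
    if check:
        _check_hermitian(H)
    psi = np.asarray(psi, complex)
    if not np.isfinite(psi).all():
        raise ValueError("non-finite wavefunction")
    if propagator.choose(H.shape[0]) == "eigh":
        w, V = scipy.linalg.eigh(H)
        phases = np.exp(-1j * TWO_PI_C * w * dt)
        proj = V.T.conj() @ psi
        if psi.ndim == 1:
            return V @ (phases * proj)
        return V @ (phases[:, None] * proj)
    if psi.ndim > 1:
        return np.stack(
            [_lanczos_expm(lambda v: H @ v, psi[:, k], dt, propagator) for k in range(psi.shape[1])],
            axis=1,
        )
    return _lanczos_expm(lambda v: H @ v, psi, dt, propagator)


def _lanczos_expm(apply_h, v: np.ndarray, dt: float, prop: Propagator) -> np.ndarray:
    """exp(-i 2 pi c H dt) v for Hermitian H via adaptive Lanczos.

    Works on arrays of any shape (flattened inner products); ``apply_h``
    must be linear and Hermitian w.r.t. the flat inner product.
    """
    norm0 = np.linalg.norm(v.ravel())
    if norm0 == 0.0:
        return v.copy()
    V = [v / norm0]
    alphas: list[float] = []
    betas: list[float] = []
    w = apply_h(V[0])
    result = None
    for j in range(prop.lanczos_max):
        alpha = float(np.vdot(V[j].ravel(), w.ravel()).real)
        alphas.append(alpha)
        w = w - alpha * V[j]
        if j > 0:
            w = w - betas[-1] * V[j - 1]
        # full reorthogonalization for numerical hygiene
        for u in V:
            w = w - np.vdot(u.ravel(), w.ravel()) * u
        beta = float(np.linalg.norm(w.ravel()))
        m = j + 1
        T = np.diag(alphas)
        if betas:
            T = T + np.diag(betas, 1) + np.diag(betas, -1)
        eT = scipy.linalg.expm(-1j * TWO_PI_C * dt * T)
        coeffs = eT[:, 0]
        err = abs(coeffs[-1]) * beta * abs(TWO_PI_C * dt)
        if beta < 1e-12 or err < prop.lanczos_tol or m == prop.lanczos_max:
            cs = coeffs.astype(v.dtype) if np.iscomplexobj(v) else coeffs
            result = sum(c * u for c, u in zip(cs, V)) * norm0
            break
        betas.append(beta)
        V.append(w / beta)
        w = apply_h(V[m])
    return result


def propagate_interval(
    H_trajectory,
    psi: np.ndarray,
    t_start: float,
    t_end: float,
    propagator: Propagator | None = None,
    diagonal_shift: float = 0.0,
) -> np.ndarray:
    """Time-ordered propagation between two times on the trajectory grid.

    Times are in fs and must align with the frame grid; the Hamiltonian of
    frame k governs the interval [k dt, (k+1) dt) (hold-constant
    convention).  ``diagonal_shift`` is subtracted from the diagonal
    (rotating-frame carrier).
    """
    if propagator is None:
        propagator = Propagator()
    dt = H_trajectory.frame_dt
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    k0 = int(round(t_start / dt))
    k1 = int(round(t_end / dt))
    if abs(k0 * dt - t_start) > 1e-9 or abs(k1 * dt - t_end) > 1e-9:
        raise ValueError("interval endpoints must lie on the frame grid")
    if k0 < 0 or k1 > H_trajectory.n_frames:
        raise ValueError("interval outside trajectory")
    for k in range(k0, k1):
        H = H_trajectory.hamiltonian_frame(k)
        if diagonal_shift:
            H = H.copy()
            H[np.diag_indices_from(H)] -= diagonal_shift
        psi = step_one_exciton(H, psi, dt, propagator, check=False)
    return psi


# ---------------------------------------------------------------------------
# two-exciton manifold


@dataclass
class TwoExcitonBasis:
    """Ordered hard-core pair basis |ij>, i<j."""

    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("two-exciton basis needs N >= 2")
        iu = np.triu_indices(self.n_sites, k=1)
        self.pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
        self.index = {p: k for k, p in enumerate(self.pairs)}

    @property
    def dim(self) -> int:
        return self.n_sites * (self.n_sites - 1) // 2


def build_two_exciton_hamiltonian(H_frame: np.ndarray) -> tuple[TwoExcitonBasis, np.ndarray]:
    """Explicit dense pair-basis Hamiltonian (for small N / validation).

    Pair energies are eps_i + eps_j; pairs sharing exactly one site couple
    by the corresponding one-exciton coupling; on-site double excitation is
    excluded (hard-core constraint).
    """
    H = np.asarray(H_frame, float)
    n = H.shape[0]
    basis = TwoExcitonBasis(n)
    eps = np.diag(H)
    H2 = np.zeros((basis.dim, basis.dim))
    for a, (i, j) in enumerate(basis.pairs):
        H2[a, a] = eps[i] + eps[j]
        for b, (k, l) in enumerate(basis.pairs):
            if b <= a:
                continue
            shared = {i, j} & {k, l}
            if len(shared) == 1:
                (s,) = shared
                m = (({i, j} - shared).pop(), ({k, l} - shared).pop())
                H2[a, b] = H2[b, a] = H[m[0], m[1]]
    return basis, H2


def pair_matrix_from_vector(c: np.ndarray, basis: TwoExcitonBasis) -> np.ndarray:
    M = np.zeros((basis.n_sites, basis.n_sites), complex)
    iu = np.triu_indices(basis.n_sites, k=1)
    M[iu] = c
    return M + M.T


def pair_vector_from_matrix(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def create_double(mu: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """mu+ |one-exciton>: symmetric pair amplitude mu_i psi_j + mu_j psi_i."""
    M = np.outer(mu, psi) + np.outer(psi, mu)
    np.fill_diagonal(M, 0.0)
    return M


def annihilate_double(mu: np.ndarray, M: np.ndarray) -> np.ndarray:
    """mu- |two-exciton>: one-exciton amplitude sum_i mu_i C_ij."""
    return M @ mu


def two_exciton_apply(eps: np.ndarray, J: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Action of the hard-core two-exciton Hamiltonian on a pair matrix.

    ``eps`` may be the (N,) site-energy vector or a precomputed (N, N)
    pair-energy matrix eps_i + eps_j.
    """
    pair = eps if eps.ndim == 2 else eps[:, None] + eps[None, :]
    out = pair * M
    JM = J @ M
    out += JM + JM.T
    np.fill_diagonal(out, 0.0)
    return out


def step_two_exciton(
    eps: np.ndarray,
    J: np.ndarray,
    M: np.ndarray,
    dt: float,
    propagator: Propagator | None = None,
) -> np.ndarray:
    """One frozen-H step of the two-exciton pair amplitude (Lanczos).

    Passing ``J`` already in the dtype of ``M`` (e.g. complex64) avoids
    per-call conversions on hot paths.
    """
    if propagator is None:
        propagator = Propagator()
    if not np.iscomplexobj(M):
        M = np.asarray(M, complex)
    Jc = J if np.iscomplexobj(J) else np.ascontiguousarray(J, dtype=M.dtype)
    epsc = np.asarray(eps)
    return _lanczos_expm(lambda X: two_exciton_apply(epsc, Jc, X), M, dt, propagator)
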