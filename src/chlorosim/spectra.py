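"""Linear absorption and absorptive 2D electronic spectra from NISE responses.

Linear absorption is the Fourier transform of the dipole autocorrelation

    I(omega) ~ Re int dt e^{i omega t} <mu(t) . U(t,0) . mu(0)>

averaged over staggered trajectory configurations and Cartesian components,
damped by exponential (homogeneous) and Gaussian (inhomogeneous)
apodization.  The absorptive 2D spectrum at zero waiting time is the sum of
rephasing and nonrephasing ground-state-bleach, stimulated-emission and
excited-state-absorption pathways, with the doubly-excited manifold treated
in the hard-core pair basis.

A final Gaussian convolution on the frequency axis models mesoscale
disorder (the ensemble spread of tube radii and orientations); the red
shift used when comparing with experiment is a reporting-stage axis shift
and never enters the Hamiltonian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
import scipy.ndimage

from .constants import C_CM_PER_FS, TWO_PI_C
from .hamiltonian import HamiltonianTrajectory
from .propagation import (
    Propagator,
    _lanczos_expm,
    create_double,
    step_one_exciton,
    step_two_exciton,
)

__all__ = [
    "ApodizationSpec",
    "SpectralCurve",
    "TwoDSpectrum",
    "linear_absorption",
    "linear_absorption_multi",
    "project_subensemble",
    "mesoscale_convolve",
    "twod_spectrum",
    "fwhm",
]


@dataclass(frozen=True)
class ApodizationSpec:
    """Time-domain damping modelling homogeneous/inhomogeneous broadening."""

    tau_homo: float = 300.0        # fs, exponential exp(-t / (2 tau_homo))
    tau_inh: float = 166.0         # fs, Gaussian exp(-t^2 / (2 tau_inh^2))
    mesoscale_sigma: float = 200.0  # cm^-1, final Gaussian convolution
    red_shift: float = 1350.0      # cm^-1, reporting-stage axis shift only

    def __post_init__(self) -> None:
        if min(self.tau_homo, self.tau_inh, self.mesoscale_sigma, self.red_shift) < 0:
            raise ValueError("apodization parameters must be >= 0")

    def window(self, t: np.ndarray) -> np.ndarray:
        w = np.ones_like(t, dtype=float)
        if self.tau_homo > 0:
            w *= np.exp(-t / (2.0 * self.tau_homo))
        if self.tau_inh > 0:
            w *= np.exp(-(t**2) / (2.0 * self.tau_inh**2))
        return w


@dataclass
class SpectralCurve:
    """1D spectrum on a strictly increasing frequency grid (cm^-1)."""

    frequency: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency axis must be strictly increasing")

    def shifted(self, red_shift: float) -> "SpectralCurve":
        """Axis shifted to the red for comparison with experiment."""
        meta = dict(self.metadata, red_shift_applied=red_shift)
        return SpectralCurve(self.frequency - red_shift, self.intensity.copy(), meta)


@dataclass
class TwoDSpectrum:
    """Absorptive 2D map: bleach (GSB+SE) positive, ESA negative."""

    omega1: np.ndarray        # pump axis, cm^-1, increasing
    omega3: np.ndarray        # probe axis, cm^-1, increasing
    amplitude: np.ndarray     # (n1, n3) real, normalized to max |amplitude| = 1
    sign_convention: str = "bleach-positive"
    metadata: dict = field(default_factory=dict)


def _config_starts(n_frames: int, window_frames: int, n_configs: int, dt: float) -> list[int]:
    if window_frames + 1 > n_frames:
        raise ValueError(
            f"coherence window of {window_frames} frames exceeds trajectory ({n_frames} frames)"
        )
    slack = n_frames - (window_frames + 1)
    if n_configs == 1:
        return [0]
    spacing = slack // (n_configs - 1) if n_configs > 1 else 0
    if spacing == 0 and slack < n_configs - 1:
        raise ValueError(
            f"trajectory too short for {n_configs} staggered configurations "
            f"plus a {window_frames}-frame coherence window"
        )
    return [i * spacing for i in range(n_configs)]


def _spectrum_from_response(
    response: np.ndarray,
    dt: float,
    carrier: float,
    apod: ApodizationSpec,
    grid_step: float = 1.0,
    span: float = 3000.0,
) -> SpectralCurve:
    """Apodize, zero-pad, Fourier transform and resample to a fixed grid."""
    n_t = len(response)
    t = np.arange(n_t) * dt
    r = response * apod.window(t)
    r[0] *= 0.5
    n_pad = 1 << max(13, int(math.ceil(math.log2(4 * n_t))))
    padded = np.zeros(n_pad, complex)
    padded[:n_t] = r
    spec = np.fft.ifft(padded).real * n_pad
    freq = carrier + np.fft.fftfreq(n_pad, d=C_CM_PER_FS * dt)
    order = np.argsort(freq)
    freq, spec = freq[order], spec[order]
    lo, hi = carrier - span, carrier + span
    grid = np.arange(math.ceil(lo), math.floor(hi) + 1, grid_step)
    intensity = np.interp(grid, freq, spec)
    return SpectralCurve(
        grid,
        intensity,
        metadata={
            "carrier": carrier,
            "dt_fs": dt,
            "tau_homo": apod.tau_homo,
            "tau_inh": apod.tau_inh,
        },
    )


def linear_absorption_multi(
    H_trajectory: HamiltonianTrajectory,
    apod: ApodizationSpec | None = None,
    coherence_time: float = 128.0,
    n_configs: int = 10,
    masks: dict[str, np.ndarray | None] | None = None,
    propagator: Propagator | None = None,
) -> dict[str, SpectralCurve]:
    """Linear absorption for several detection masks in one propagation pass.

    The one-exciton propagation is shared; each named mask restricts the
    *detection* dipole to a subensemble of sites (``None`` = all sites), so
    complementary masks sum exactly to the total spectrum.
    """
    if apod is None:
        apod = ApodizationSpec()
    if propagator is None:
        propagator = Propagator()
    if masks is None:
        masks = {"total": None}
    traj = H_trajectory
    dt = traj.frame_dt
    n_steps = int(round(coherence_time / dt))
    starts = _config_starts(traj.n_frames, n_steps, n_configs, dt)
    carrier = float(traj.diagonal.mean())
    n = traj.n_sites

    prepared: dict[str, np.ndarray | None] = {}
    for name, mask in masks.items():
        if mask is not None:
            mask = np.asarray(mask, bool)
            if mask.shape != (n,):
                raise ValueError(f"mask '{name}' has shape {mask.shape}, expected ({n},)")
            if not mask.any():
                import warnings

                warnings.warn(f"empty subensemble mask '{name}': zero spectrum", stacklevel=2)
        prepared[name] = mask

    fast = n > propagator.eigh_threshold
    responses = {name: np.zeros(n_steps + 1, complex) for name in prepared}
    for k0 in starts:
        mu0 = np.asarray(traj.dipole_vectors[k0], float)           # (N, 3)
        psi = mu0.astype(np.complex64 if fast else complex)        # 3 Cartesian columns
        for j in range(n_steps + 1):
            mu_t = np.asarray(traj.dipole_vectors[k0 + j], float)
            for name, mask in prepared.items():
                det = mu_t if mask is None else mu_t * mask[:, None]
                responses[name][j] += np.sum(det * psi)
            if j < n_steps:
                if fast:
                    # float32 matvec path: split real/imag to avoid upcasts
                    Hs = np.array(traj.coupling_frame(k0 + j), np.float32, copy=True)
                    Hs[np.diag_indices_from(Hs)] = traj.diagonal[k0 + j] - carrier
                    apply = lambda v: Hs @ v.real + 1j * (Hs @ v.imag)
                    psi = np.stack(
                        [_lanczos_expm(apply, psi[:, c], dt, propagator) for c in range(psi.shape[1])],
                        axis=1,
                    )
                else:
                    H = traj.hamiltonian_frame(k0 + j)
                    H[np.diag_indices_from(H)] -= carrier
                    psi = step_one_exciton(H, psi, dt, propagator, check=False)
    out = {}
    for name, resp in responses.items():
        resp /= len(starts)
        curve = _spectrum_from_response(resp, dt, carrier, apod)
        curve.metadata.update(n_configs=len(starts), coherence_time=coherence_time, mask=name)
        out[name] = curve
    return out


def linear_absorption(
    H_trajectory: HamiltonianTrajectory,
    apod: ApodizationSpec | None = None,
    coherence_time: float = 128.0,
    n_configs: int = 10,
    mask: np.ndarray | None = None,
    propagator: Propagator | None = None,
) -> SpectralCurve:
    """Isotropically averaged linear absorption of the Qy exciton band.

    The dipole autocorrelation is averaged over ``n_configs`` staggered
    starting points and the three Cartesian components (analytic isotropic
    average); ``mask`` restricts the *detection* dipole to a subensemble of
    sites, so that complementary masks sum exactly to the total spectrum.
    """
    curves = linear_absorption_multi(
        H_trajectory, apod, coherence_time, n_configs, {"curve": mask}, propagator
    )
    return curves["curve"]


def project_subensemble(
    H_trajectory: HamiltonianTrajectory,
    mask: np.ndarray,
    apod: ApodizationSpec | None = None,
    **kwargs,
) -> SpectralCurve:
    """Spectral contribution of a site subensemble (one dipole factor masked)."""
    return linear_absorption(H_trajectory, apod, mask=np.asarray(mask, bool), **kwargs)


def mesoscale_convolve(curve: SpectralCurve, sigma: float) -> SpectralCurve:
    """Gaussian convolution on the frequency axis; sigma = 0 is the identity.

    Models the inhomogeneous ensemble of tube radii and orientations; total
    integrated intensity is conserved.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return SpectralCurve(curve.frequency.copy(), curve.intensity.copy(), dict(curve.metadata))
    step = float(curve.frequency[1] - curve.frequency[0])
    out = scipy.ndimage.gaussian_filter1d(curve.intensity, sigma / step, mode="constant", cval=0.0)
    meta = dict(curve.metadata, mesoscale_sigma=sigma)
    return SpectralCurve(curve.frequency.copy(), out, meta)


def fwhm(curve: SpectralCurve) -> tuple[float, float]:
    """(width, peak position) via interpolated half-maximum crossings."""
    y = curve.intensity
    x = curve.frequency
    k = int(np.argmax(y))
    half = y[k] / 2.0
    # walk left
    i = k
    while i > 0 and y[i] > half:
        i -= 1
    if y[i] == y[i + 1]:
        left = x[i]
    else:
        left = x[i] + (half - y[i]) / (y[i + 1] - y[i]) * (x[i + 1] - x[i])
    j = k
    while j < len(y) - 1 and y[j] > half:
        j += 1
    if y[j] == y[j - 1]:
        right = x[j]
    else:
        right = x[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (x[j] - x[j - 1])
    return float(right - left), float(x[k])


# ---------------------------------------------------------------------------
# 2DES at zero waiting time


def _random_unit_vectors(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def twod_spectrum(
    H_trajectory: HamiltonianTrajectory,
    apod: ApodizationSpec | None = None,
    coherence_time: float = 192.0,
    t2: float = 0.0,
    n_configs: int = 10,
    sample_dt: float = 8.0,
    polarization: str = "parallel",
    seed: int = 0,
    max_sites: int = 600,
    propagator: Propagator | None = None,
    pad: int = 1024,
    span: tuple[float, float] = (-2000.0, 1600.0),
    normalize: bool = True,
    carrier: float | None = None,
) -> TwoDSpectrum:
    """Absorptive parallel-polarization 2DES at zero waiting time.

    Sums rephasing and nonrephasing GSB, SE and ESA pathways; the ESA ket is
    propagated in the hard-core two-exciton pair basis (matrix-free Lanczos).
    The isotropic parallel (ZZZZ) average is approximated by drawing one
    random lab polarization direction per disorder configuration (seeded),
    which converges to the analytic average with the configuration count.
    The response is sampled every ``sample_dt`` fs in a rotating frame at
    the band centre while the wavefunctions advance at the trajectory frame
    step.
    """
    if apod is None:
        apod = ApodizationSpec()
    if propagator is None:
        propagator = Propagator(lanczos_tol=1e-7)
    if t2 != 0.0:
        raise NotImplementedError("only zero waiting time (t2 = 0) is supported")
    if polarization != "parallel":
        raise NotImplementedError("only the parallel (ZZZZ) pulse sequence is supported")
    traj = H_trajectory
    n = traj.n_sites
    if n > max_sites:
        raise ValueError(
            f"two-exciton treatment infeasible for N = {n} sites (guard at {max_sites}); "
            "reduce the system or raise max_sites explicitly"
        )
    dt = traj.frame_dt
    stride = int(round(sample_dt / dt))
    if abs(stride * dt - sample_dt) > 1e-9 or stride < 1:
        raise ValueError("sample_dt must be an integer multiple of the frame step")
    n_t = int(round(coherence_time / sample_dt)) + 1
    window = 2 * (n_t - 1) * stride
    starts = _config_starts(traj.n_frames, window, n_configs, dt)
    if carrier is None:
        carrier = float(traj.diagonal.mean())
    pols = _random_unit_vectors(len(starts), seed)

    R_r = np.zeros((n_t, n_t), complex)
    R_nr = np.zeros((n_t, n_t), complex)

    for cfg, k0 in enumerate(starts):
        pol = pols[cfg]
        _accumulate_2d_config(traj, k0, pol, carrier, stride, n_t, propagator, R_r, R_nr)
    R_r /= len(starts)
    R_nr /= len(starts)

    t_axis = np.arange(n_t) * sample_dt
    w = apod.window(t_axis)
    w[0] *= 0.5
    R_r = R_r * w[:, None] * w[None, :]
    R_nr = R_nr * w[:, None] * w[None, :]

    # rephasing: e^{+i w1 t1}, e^{-i w3 t3} -> fft along t1, ifft along t3
    S_r = np.fft.fft(np.fft.ifft(R_r, n=pad, axis=1) * pad, n=pad, axis=0)
    S_nr = np.fft.ifft(np.fft.ifft(R_nr, n=pad, axis=1) * pad, n=pad, axis=0) * pad
    total = (S_r + S_nr).real

    freq = np.fft.fftfreq(pad, d=C_CM_PER_FS * sample_dt)
    order = np.argsort(freq)
    total = total[np.ix_(order, order)]
    w1 = carrier + freq[order]
    w3 = carrier + freq[order]

    keep1 = (w1 >= carrier + span[0]) & (w1 <= carrier + span[1])
    keep3 = (w3 >= carrier + span[0]) & (w3 <= carrier + span[1])
    total = total[np.ix_(keep1, keep3)]
    w1, w3 = w1[keep1], w3[keep3]

    if normalize:
        peak = np.abs(total).max()
        if peak > 0:
            total = total / peak
    return TwoDSpectrum(
        omega1=w1,
        omega3=w3,
        amplitude=total,
        metadata={
            "carrier": carrier,
            "coherence_time": coherence_time,
            "sample_dt": sample_dt,
            "n_configs": len(starts),
            "seed": seed,
            "tau_homo": apod.tau_homo,
            "tau_inh": apod.tau_inh,
            "red_shift": apod.red_shift,
        },
    )


def _accumulate_2d_config(
    traj: HamiltonianTrajectory,
    k0: int,
    pol: np.ndarray,
    carrier: float,
    stride: int,
    n_t: int,
    propagator: Propagator,
    R_r: np.ndarray,
    R_nr: np.ndarray,
) -> None:
    """Add one disorder configuration's pathways to the response matrices."""
    n = traj.n_sites
    window = 2 * (n_t - 1) * stride
    n_samples = 2 * (n_t - 1) + 1

    # per-frame data in the window (complex64 pipeline on the hot path)
    cache: list = [None] * window

    def frame_data(j):
        if cache[j] is None:
            k = k0 + j
            J = np.asarray(traj.coupling_frame(k), np.float32)
            e = np.asarray(traj.diagonal[k], float) - carrier
            H = J.astype(np.float64) + np.diag(e)
            wv, V = scipy.linalg.eigh(H)
            U = (V * np.exp(-1j * TWO_PI_C * wv * traj.frame_dt)[None, :]) @ V.T
            pair = (e[:, None] + e[None, :]).astype(np.float32)
            cache[j] = (pair, np.ascontiguousarray(J, np.complex64), U.astype(np.complex64))
        return cache[j]

    def xvec(sample_idx):
        mu = np.asarray(traj.dipole_vectors[k0 + sample_idx * stride], float)
        return mu @ pol

    # one-exciton wavepacket from pulse 1, stored at every sample point
    x0 = xvec(0)
    A = np.empty((n_samples, n), np.complex64)
    psi = x0.astype(np.complex64)
    A[0] = psi
    for s in range(1, n_samples):
        for sub in range(stride):
            _, _, U = frame_data((s - 1) * stride + sub)
            psi = U @ psi
        A[s] = psi

    for i1 in range(n_t):
        x1 = xvec(i1)
        c_nr = complex(x1 @ A[i1])
        c_r = np.conj(c_nr)
        s_r1 = float(x1 @ x1)

        ket = x1.astype(np.complex64)                 # U(tau3, tau1) x1
        F_r = create_double(x1, x1).astype(np.complex64)
        F_nr = create_double(x1, np.asarray(A[i1], complex)).astype(np.complex64)

        for j3 in range(n_t):
            s_abs = i1 + j3
            x3 = xvec(s_abs)
            emit = complex(x3 @ ket)
            R_r[i1, j3] += 2.0 * c_r * emit
            R_nr[i1, j3] += c_nr * emit + s_r1 * complex(x3 @ A[s_abs])
            # ESA: bra is the pulse-1 wavepacket (rephasing) or U(t3,t1)x1
            R_r[i1, j3] -= complex(np.vdot(A[s_abs], F_r @ x3.astype(np.float32)))
            R_nr[i1, j3] -= complex(np.vdot(ket, F_nr @ x3.astype(np.float32)))
            if j3 < n_t - 1:
                for sub in range(stride):
                    pair, Jc, U = frame_data((i1 + j3) * stride + sub)
                    ket = U @ ket
                    F_r = step_two_exciton(pair, Jc, F_r, traj.frame_dt, propagator)
                    F_nr = step_two_exciton(pair, Jc, F_nr, traj.frame_dt, propagator)
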