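"""Reduction of the 2DES map to transient-absorption observables.

The map is summarized the way 2D experiments are tabulated: the pump-probe
spectrum (integral over the pump axis), a vertical slice at the bright-state
pump frequency, the diagonal slice, and for each curve the absolute
intensity ratio between its negative (ESA) and positive (bleach) extrema,
their separation along the probe axis, and the full width at half maximum
of the dominant bleach feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectralCurve, TwoDSpectrum

__all__ = ["SliceMetrics", "pump_probe", "slice_spectrum", "peak_metrics"]


@dataclass
class SliceMetrics:
    """|I_min/I_max|, |delta omega (min - max)| and bleach fwhm of one curve."""

    intensity_ratio: float | None     # dimensionless, >= 0
    peak_separation: float | None     # cm^-1, >= 0
    fwhm: float | None                # cm^-1, of the dominant positive feature
    max_position: float | None = None
    min_position: float | None = None


def pump_probe(spectrum: TwoDSpectrum) -> SpectralCurve:
    """Pump-probe spectrum: trapezoidal integral of the map over omega1."""
    intensity = np.trapezoid(spectrum.amplitude, x=spectrum.omega1, axis=0)
    return SpectralCurve(
        spectrum.omega3.copy(),
        intensity,
        metadata={"kind": "pump-probe", **spectrum.metadata},
    )


def slice_spectrum(
    spectrum: TwoDSpectrum,
    kind: str = "vertical",
    omega1: float | None = None,
) -> SpectralCurve:
    """Vertical slice at a pump frequency, or the diagonal omega1 = omega3.

    ``omega1=None`` for a vertical slice uses the pump frequency of the
    map's positive maximum (the bright-state slice).  Vertical slices
    interpolate linearly between the two adjacent pump grid lines; the
    diagonal is interpolated along omega1 at each omega3.
    """
    a = spectrum.amplitude
    if kind == "diagonal":
        vals = np.empty_like(spectrum.omega3)
        for j, w in enumerate(spectrum.omega3):
            vals[j] = _interp_along_axis0(a[:, j], spectrum.omega1, w)
        return SpectralCurve(spectrum.omega3.copy(), vals, metadata={"kind": "diagonal"})
    if kind != "vertical":
        raise ValueError("kind must be 'vertical' or 'diagonal'")
    if omega1 is None:
        i, _ = np.unravel_index(np.argmax(a), a.shape)
        omega1 = float(spectrum.omega1[i])
    if not spectrum.omega1[0] <= omega1 <= spectrum.omega1[-1]:
        raise ValueError(f"omega1 = {omega1} outside the pump axis")
    vals = np.empty_like(spectrum.omega3)
    for j in range(len(spectrum.omega3)):
        vals[j] = _interp_along_axis0(a[:, j], spectrum.omega1, omega1)
    return SpectralCurve(
        spectrum.omega3.copy(), vals, metadata={"kind": "vertical", "omega1": omega1}
    )


def _interp_along_axis0(col: np.ndarray, axis: np.ndarray, x: float) -> float:
    return float(np.interp(x, axis, col))


def _refine_extremum(x: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-grid extremum via a local quadratic through three points."""
    if k == 0 or k == len(x) - 1:
        return float(x[k]), float(y[k])
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    if denom == 0.0:
        return float(x[k]), float(y[k])
    delta = 0.5 * (y[k - 1] - y[k + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = x[k + 1] - x[k]
    xr = x[k] + delta * step
    yr = y[k] - 0.25 * (y[k - 1] - y[k + 1]) * delta
    return float(xr), float(yr)


def _fwhm_positive(x: np.ndarray, y: np.ndarray, k: int) -> float | None:
    half = y[k] / 2.0
    i = k
    while i > 0 and y[i] > half:
        i -= 1
    if y[i] > half:
        return None
    left = x[i] + (half - y[i]) / (y[i + 1] - y[i]) * (x[i + 1] - x[i])
    j = k
    while j < len(y) - 1 and y[j] > half:
        j += 1
    if y[j] > half:
        return None
    right = x[j - 1] + (half - y[j - 1]) / (y[j] - y[j - 1]) * (x[j] - x[j - 1])
    return float(right - left)


def peak_metrics(curve: SpectralCurve) -> SliceMetrics:
    """Extremum ratio, separation and bleach fwhm of one 1D transient curve.

    Extrema are refined by a 3-point parabolic fit; the fwhm refers to the
    dominant positive (GSB/SE) feature via interpolated half-maximum
    crossings.  If the curve lacks a negative extremum, the ratio and
    separation are reported as None (partial result).
    """
    x = curve.frequency
    y = curve.intensity
    if np.allclose(y, y[0]):
        raise ValueError("flat curve: no extrema")
    k_max = int(np.argmax(y))
    x_max, y_max = _refine_extremum(x, y, k_max)
    width = _fwhm_positive(x, y, k_max)
    if y.min() >= 0.0 or y_max <= 0.0:
        return SliceMetrics(None, None, width, max_position=x_max)
    k_min = int(np.argmin(y))
    x_min, y_min = _refine_extremum(x, y, k_min)
    return SliceMetrics(
        intensity_ratio=abs(y_min / y_max),
        peak_separation=abs(x_min - x_max),
        fwhm=width,
        max_position=x_max,
        min_position=x_min,
    )
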