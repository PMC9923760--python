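"""Orientational and energy/coupling correlation functions and their fits.

The renormalized orientational correlation function

    C_or(t) = (2/5) < P2( u(t0) . u(t0 + t) ) >

(averaged over sites and time origins) starts at 0.4 — the value of the
spectrally relevant anisotropy for perfect correlation — and its long-time
plateau encodes the wobble cone of the transition dipoles.

Scalar fluctuations (transition energies, coupling strengths) are
characterized by the temporal autocovariance of deviations from the
ensemble mean, fitted to a multiexponential plus a static offset:

    C(t) = sigma_static^2 + sum_i sigma_i^2 exp(-t / tau_i),

with the slowest component listed first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

__all__ = [
    "CorrelationSeries",
    "MultiExpFit",
    "orientation_correlation",
    "autocorrelation",
    "fit_multiexponential",
]


@dataclass
class CorrelationSeries:
    """Lag-resolved correlation values with per-lag sample counts."""

    lags: np.ndarray        # fs
    values: np.ndarray
    n_samples: np.ndarray   # averaging count per lag
    kind: str = "autocovariance"

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.values = np.asarray(self.values, float)
        self.n_samples = np.asarray(self.n_samples)


@dataclass
class MultiExpFit:
    """Static offset + multiexponential decomposition of an autocovariance."""

    sigma_static: float                     # cm^-1
    components: list[tuple[float, float]]   # [(sigma_i cm^-1, tau_i fs)], slowest first
    gof: float                              # rms residual / value at lag 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.full_like(t, self.sigma_static**2)
        for s, tau in self.components:
            out += s**2 * np.exp(-t / tau)
        return out


def orientation_correlation(
    dipoles: np.ndarray,
    frame_dt: float,
    mask: np.ndarray | None = None,
    max_lag: int | None = None,
    lag_stride: int = 1,
) -> CorrelationSeries:
    """(2/5) <P2(cos Theta(t))> over sites in ``mask`` and all time origins."""
    d = np.asarray(dipoles, float)
    n_frames, n_sites = d.shape[0], d.shape[1]
    if mask is not None:
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("empty subensemble mask")
        d = d[:, mask, :]
        n_sites = d.shape[1]
    norms = np.linalg.norm(d, axis=2)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("dipoles must be unit vectors")
    if max_lag is None:
        max_lag = n_frames - 1
    lags = np.arange(0, max_lag + 1, lag_stride)
    values = np.empty(len(lags))
    counts = np.empty(len(lags), dtype=np.int64)
    for idx, lag in enumerate(lags):
        if lag == 0:
            values[idx] = 0.4
            counts[idx] = n_frames * n_sites
            continue
        cos = np.einsum("tns,tns->tn", d[:-lag], d[lag:])
        p2 = 1.5 * cos**2 - 0.5
        values[idx] = 0.4 * p2.mean()
        counts[idx] = p2.size
    return CorrelationSeries(lags * frame_dt, values, counts, kind="orientation")


def autocorrelation(
    series: np.ndarray,
    frame_dt: float,
    max_lag: int | None = None,
    demean: str = "ensemble",
) -> CorrelationSeries:
    """Site- and origin-averaged autocovariance of a (frames, N) series.

    ``demean="ensemble"`` subtracts the global mean, so frozen per-site
    offsets (static disorder, class structure) appear as a long-time
    plateau; ``demean="site"`` removes each site's own time average and
    isolates the dynamic components.  A constant series is flagged and
    returns zeros.
    """
    x = np.atleast_2d(np.asarray(series, float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    n_frames, n_sites = x.shape
    if demean == "ensemble":
        x = x - x.mean()
    elif demean == "site":
        x = x - x.mean(axis=0, keepdims=True)
    else:
        raise ValueError("demean must be 'ensemble' or 'site'")
    if max_lag is None:
        max_lag = n_frames - 1
    var = float((x**2).mean())
    lags = np.arange(max_lag + 1)
    if var == 0.0:
        return CorrelationSeries(
            lags * frame_dt,
            np.zeros(max_lag + 1),
            np.full(max_lag + 1, n_sites * n_frames),
            kind="constant-series",
        )
    # FFT-based autocovariance per site, averaged
    n_pad = 1 << int(np.ceil(np.log2(2 * n_frames)))
    X = np.fft.rfft(x, n=n_pad, axis=0)
    acf = np.fft.irfft((X * X.conj()).real, n=n_pad, axis=0)[: max_lag + 1]
    acf = acf.sum(axis=1)
    counts = (n_frames - lags) * n_sites
    values = acf / (n_frames - lags)
    values /= n_sites
    return CorrelationSeries(lags * frame_dt, values, counts)


def fit_multiexponential(
    series: CorrelationSeries,
    n_components: int = 2,
    static_term: bool = True,
    fit_fraction: float = 1.0 / 3.0,
) -> MultiExpFit:
    """Bounded least-squares fit of sigma_static^2 + sum sigma_i^2 e^(-t/tau_i).

    Lags beyond ``fit_fraction`` of the series are discarded (long-lag
    estimates are statistically unreliable).  A deterministic multi-start
    grid of log-spaced time constants (10 fs - 5 ps) guards against local
    minima; non-convergence is reported in the result, never silent.
    """
    n_fit = max(int(len(series.lags) * fit_fraction), n_components * 3 + 2)
    t = series.lags[:n_fit]
    y = series.values[:n_fit]
    if t[-1] <= 0:
        raise ValueError("series too short to fit")
    scale = max(abs(y[0]), 1e-30)

    def model(params: np.ndarray) -> np.ndarray:
        c0 = params[0] if static_term else 0.0
        out = np.full_like(t, c0)
        for i in range(n_components):
            a, tau = params[1 + 2 * i], params[2 + 2 * i]
            out = out + a * np.exp(-t / tau)
        return out

    def residuals(params: np.ndarray) -> np.ndarray:
        return (model(params) - y) / scale

    tau_grid = np.geomspace(10.0, 5000.0, 6)
    best = None
    amp0 = max(y[0] - (y[-1] if static_term else 0.0), scale * 0.1) / n_components
    starts = []
    if n_components == 1:
        starts = [[tau] for tau in tau_grid]
    else:
        for i, tau_slow in enumerate(tau_grid):
            for tau_fast in tau_grid[: i + 1]:
                taus = np.geomspace(tau_slow, max(tau_fast, 10.0), n_components)
                starts.append(list(taus))
    lower = [0.0] + [0.0, 1.0] * n_components
    upper = [np.inf] * (1 + 2 * n_components)
    for taus in starts:
        p0 = [max(y[-1], 0.0) if static_term else 0.0]
        for tau in taus:
            p0 += [amp0, tau]
        res = scipy.optimize.least_squares(
            residuals, p0, bounds=(lower, upper), max_nfev=2000
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e-2:
        return MultiExpFit(
            sigma_static=float("nan"),
            components=[],
            gof=float("inf"),
            converged=False,
            diagnostics={"message": getattr(best, "message", "no fit")},
        )
    p = best.x
    comps = sorted(
        [(math_sqrt(p[1 + 2 * i]), p[2 + 2 * i]) for i in range(n_components)],
        key=lambda st: -st[1],
    )
    resid = model(p) - y
    return MultiExpFit(
        sigma_static=math_sqrt(p[0]) if static_term else 0.0,
        components=[(float(s), float(tau)) for s, tau in comps],
        gof=float(np.sqrt(np.mean(resid**2)) / scale),
        converged=bool(best.success),
        diagnostics={"cost": float(best.cost), "n_fit": int(n_fit)},
    )


def math_sqrt(v: float) -> float:
    return float(np.sqrt(max(v, 0.0)))
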