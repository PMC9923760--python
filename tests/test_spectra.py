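import numpy as np
import pytest

from chlorosim.spectra import (
    ApodizationSpec,
    SpectralCurve,
    fwhm,
    linear_absorption,
    linear_absorption_multi,
    mesoscale_convolve,
    project_subensemble,
    twod_spectrum,
)
from tests.conftest import static_hamiltonian

APOD = ApodizationSpec()
FAST_APOD = ApodizationSpec(tau_homo=40.0, tau_inh=50.0)  # decays within the window


class TestLinearAbsorption:
    def test_single_site_line_at_site_energy(self):
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0.0, 0, 1]])
        curve = linear_absorption(traj, APOD, n_configs=1)
        _, peak = fwhm(curve)
        assert peak == pytest.approx(15390.0, abs=2.0)

    def test_dimer_bright_line_at_w0_plus_J(self):
        J = -300.0
        traj = static_hamiltonian(
            [15390.0, 15390.0], [[0.0, J], [J, 0.0]], [[0, 0, 1.0], [0, 0, 1.0]]
        )
        curve = linear_absorption(traj, APOD, n_configs=1)
        width, peak = fwhm(curve)
        assert peak == pytest.approx(15390.0 + J, abs=2.0)
        # single bright line: nothing at the dark-state position beyond the
        # sinc ringing of the 128-fs truncation (few-percent oscillations)
        dark = np.interp(15390.0 - J, curve.frequency, curve.intensity)
        assert abs(dark) < 0.08 * curve.intensity.max()

    def test_sum_rule_under_unitary_mixing(self):
        """Integrated unapodized intensity is conserved by coupling."""
        bare = ApodizationSpec(tau_homo=0.0, tau_inh=0.0)
        dip = [[0, 0, 1.0], [0.6, 0.8, 0.0]]
        uncoupled = static_hamiltonian([15300.0, 15500.0], np.zeros((2, 2)), dip)
        coupled = static_hamiltonian([15300.0, 15500.0], [[0, -250.0], [-250.0, 0]], dip)
        a = linear_absorption(uncoupled, bare, n_configs=1)
        b = linear_absorption(coupled, bare, n_configs=1)
        ia = np.trapezoid(a.intensity, a.frequency)
        ib = np.trapezoid(b.intensity, b.frequency)
        # the finite output window clips slightly different truncation tails
        assert ib == pytest.approx(ia, rel=0.02)

    def test_coherence_window_exceeding_trajectory(self):
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0, 0, 1.0]], frames=10)
        with pytest.raises(ValueError, match="exceeds trajectory"):
            linear_absorption(traj, APOD, coherence_time=128.0, n_configs=1)

    def test_apodization_preserves_centroid_of_symmetric_line(self):
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0, 0, 1.0]])
        for apod in (APOD, ApodizationSpec(tau_homo=80.0, tau_inh=500.0)):
            c = linear_absorption(traj, apod, n_configs=1)
            centroid = (c.frequency * c.intensity).sum() / c.intensity.sum()
            assert centroid == pytest.approx(15390.0, abs=3.0)


class TestProjection:
    def test_full_mask_equals_total(self):
        traj = static_hamiltonian(
            [15300.0, 15500.0], [[0, -100.0], [-100.0, 0]], [[0, 0, 1.0], [0, 0, 1.0]]
        )
        total = linear_absorption(traj, APOD, n_configs=1)
        masked = project_subensemble(traj, np.array([True, True]), APOD, n_configs=1)
        np.testing.assert_allclose(masked.intensity, total.intensity, atol=1e-9)

    def test_complementary_masks_sum_to_total(self):
        traj = static_hamiltonian(
            [15300.0, 15500.0, 15400.0],
            [[0, -100.0, 30.0], [-100.0, 0, -60.0], [30.0, -60.0, 0]],
            [[0, 0, 1.0], [0, 0.2, 0.98], [0.1, 0, 0.99]],
        )
        curves = linear_absorption_multi(
            traj, APOD, n_configs=1,
            masks={"total": None,
                   "a": np.array([True, False, True]),
                   "b": np.array([False, True, False])},
        )
        np.testing.assert_allclose(
            curves["a"].intensity + curves["b"].intensity,
            curves["total"].intensity, atol=1e-8,
        )

    def test_empty_mask_warns_and_zeroes(self):
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0, 0, 1.0]])
        with pytest.warns(UserWarning, match="empty subensemble"):
            c = project_subensemble(traj, np.array([False]), APOD, n_configs=1)
        assert np.allclose(c.intensity, 0.0)


class TestMesoscaleConvolve:
    def test_sigma_zero_is_identity(self):
        c = SpectralCurve(np.arange(100.0), np.exp(-((np.arange(100.0) - 50) ** 2) / 30))
        out = mesoscale_convolve(c, 0.0)
        np.testing.assert_array_equal(out.intensity, c.intensity)

    def test_delta_line_becomes_gaussian_of_known_fwhm(self):
        grid = np.arange(14000.0, 18001.0)
        y = np.zeros_like(grid)
        y[2000] = 1.0
        out = mesoscale_convolve(SpectralCurve(grid, y), 200.0)
        width, _ = fwhm(out)
        assert width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 200.0, rel=0.01)

    def test_intensity_conserved(self):
        grid = np.arange(14000.0, 18001.0)
        y = np.exp(-((grid - 16000.0) ** 2) / (2 * 150.0**2))
        out = mesoscale_convolve(SpectralCurve(grid, y), 200.0)
        assert out.intensity.sum() == pytest.approx(y.sum(), rel=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            mesoscale_convolve(SpectralCurve(np.arange(5.0), np.ones(5)), -1.0)


class TestTwoDSpectrum:
    def test_single_site_no_esa(self):
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0, 0, 1.0]])
        s = twod_spectrum(traj, FAST_APOD, coherence_time=96.0, n_configs=1, sample_dt=4.0, pad=512)
        i, j = np.unravel_index(np.argmax(s.amplitude), s.amplitude.shape)
        assert s.omega1[i] == pytest.approx(15390.0, abs=20.0)
        assert s.omega3[j] == pytest.approx(15390.0, abs=20.0)
        assert s.amplitude.min() > -0.01  # no negative (ESA) feature

    def test_dimer_esa_displaced_by_two_J(self):
        J = -300.0
        traj = static_hamiltonian(
            [15390.0, 15390.0], [[0.0, J], [J, 0.0]], [[0, 0, 1.0], [0, 0, 1.0]]
        )
        s = twod_spectrum(
            traj, ApodizationSpec(tau_homo=1000.0, tau_inh=1000.0),
            coherence_time=192.0, n_configs=1, sample_dt=8.0, pad=512,
        )
        a = s.amplitude
        ip, jp = np.unravel_index(np.argmax(a), a.shape)
        im, jm = np.unravel_index(np.argmin(a), a.shape)
        assert s.omega3[jp] == pytest.approx(15390.0 + J, abs=20.0)
        assert (s.omega3[jm] - s.omega3[jp]) == pytest.approx(2 * abs(J), abs=25.0)
        assert a[im, jm] < -0.3  # ESA is negative

    def test_uncoupled_sites_reduce_to_sum_of_singles(self):
        """Pathway cancellation: no net cross response for uncoupled sites."""
        carrier = 15400.0
        kw = dict(apod=FAST_APOD, coherence_time=96.0, n_configs=1,
                  sample_dt=4.0, pad=512, normalize=False, carrier=carrier)
        pair = static_hamiltonian(
            [15200.0, 15600.0], np.zeros((2, 2)), [[0, 0, 1.0], [0, 0, 1.0]]
        )
        s_pair = twod_spectrum(pair, **kw)
        parts = []
        for eps in (15200.0, 15600.0):
            one = static_hamiltonian([eps], np.zeros((1, 1)), [[0, 0, 1.0]])
            parts.append(twod_spectrum(one, **kw).amplitude)
        np.testing.assert_allclose(
            s_pair.amplitude, parts[0] + parts[1],
            atol=2e-3 * np.abs(s_pair.amplitude).max(),
        )

    def test_absorptive_sum_for_static_two_level(self):
        """Rephasing + nonrephasing of a two-level toy is purely absorptive:
        the map equals the product of 1D absorptive lineshapes (no twist)."""
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0, 0, 1.0]])
        s = twod_spectrum(traj, FAST_APOD, coherence_time=96.0, n_configs=1, sample_dt=4.0, pad=512)
        a = s.amplitude
        i, j = np.unravel_index(np.argmax(a), a.shape)
        outer = np.outer(a[:, j], a[i, :]) / a[i, j]
        np.testing.assert_allclose(a, outer, atol=0.02)

    def test_nonzero_waiting_time_rejected(self):
        traj = static_hamiltonian([15390.0], np.zeros((1, 1)), [[0, 0, 1.0]])
        with pytest.raises(NotImplementedError):
            twod_spectrum(traj, FAST_APOD, t2=50.0)

    def test_infeasible_size_guard(self):
        traj = static_hamiltonian([15390.0] * 4, np.zeros((4, 4)), [[0, 0, 1.0]] * 4)
        with pytest.raises(ValueError, match="infeasible"):
            twod_spectrum(traj, FAST_APOD, max_sites=3)


class TestFwhm:
    def test_known_gaussian(self):
        grid = np.arange(-600.0, 601.0)
        sigma = 120.0
        c = SpectralCurve(grid, np.exp(-(grid**2) / (2 * sigma**2)))
        width, peak = fwhm(c)
        assert width == pytest.approx(2 * np.sqrt(2 * np.log(2)) * sigma, rel=0.005)
        assert peak == 0.0
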