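import numpy as np
import pytest

from chlorosim.analysis import (
    binned_profile,
    coupling_for_edl,
    diagonalize,
    donor_character,
    edl_from_2d,
    ipr,
    oscillator_strengths,
    superradiance_histogram,
)


def ring_hamiltonian(n, J=-100.0, eps=15000.0):
    H = np.full((n, n), 0.0)
    for i in range(n):
        H[i, i] = eps
        H[i, (i + 1) % n] = H[(i + 1) % n, i] = J
    return H


class TestDiagonalize:
    def test_diagonal_hamiltonian_identity_coefficients(self):
        eps = np.array([1.0, 5.0, 9.0])
        mu = np.eye(3)
        states = diagonalize(np.diag(eps), mu)
        np.testing.assert_allclose(np.abs(states.coefficients), np.eye(3), atol=1e-12)
        np.testing.assert_allclose(states.energies, eps)

    def test_two_site_mixing_angle_closed_form(self):
        e1, e2, J = 100.0, 300.0, -80.0
        H = np.array([[e1, J], [J, e2]])
        states = diagonalize(H, np.eye(3)[:2])
        theta = 0.5 * np.arctan2(2 * J, e1 - e2)
        expected = abs(np.cos(theta))
        assert max(abs(states.coefficients[0, 0]), abs(states.coefficients[0, 1])) == pytest.approx(
            max(expected, abs(np.sin(theta))), rel=1e-10
        )

    def test_homogeneous_ring_superradiant_state(self):
        """Parallel-dipole N-ring: one state carries sqrt(N) mu, rest dark."""
        n = 12
        mu = np.tile([0.0, 0.0, 2.0], (n, 1))
        states = diagonalize(ring_hamiltonian(n), mu)
        ratios = np.linalg.norm(states.state_dipoles, axis=1) / 2.0
        ratios.sort()
        assert ratios[-1] == pytest.approx(np.sqrt(n), rel=1e-10)
        np.testing.assert_allclose(ratios[:-1], 0.0, atol=1e-9)

    def test_non_hermitian_rejected(self):
        H = np.array([[0.0, 1.0], [5.0, 0.0]])
        with pytest.raises(ValueError, match="Hermitian"):
            diagonalize(H, np.zeros((2, 3)))

    def test_unitary_dipole_sum_rule(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((20, 20))
        H = A + A.T
        mu = rng.standard_normal((20, 3))
        states = diagonalize(H, mu)
        assert (states.state_dipoles**2).sum() == pytest.approx((mu**2).sum(), rel=1e-10)


class TestDonorCharacter:
    def test_all_donors_gives_one(self):
        states = diagonalize(ring_hamiltonian(6), np.ones((6, 3)))
        np.testing.assert_allclose(donor_character(states, np.ones(6)), 1.0, atol=1e-12)

    def test_no_donors_gives_zero(self):
        states = diagonalize(ring_hamiltonian(6), np.ones((6, 3)))
        np.testing.assert_allclose(donor_character(states, np.zeros(6)), 0.0, atol=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((30, 30))
        states = diagonalize(A + A.T, rng.standard_normal((30, 3)))
        psi = donor_character(states, rng.random(30) < 0.5)
        assert np.all(psi >= 0.0) and np.all(psi <= 1.0)

    def test_flag_length_mismatch(self):
        states = diagonalize(ring_hamiltonian(4), np.ones((4, 3)))
        with pytest.raises(ValueError, match="every site"):
            donor_character(states, np.ones(3))

    def test_binned_average_weighted_by_state_count(self):
        states = diagonalize(np.diag([0.0, 1.0, 1.2, 5.0]), np.ones((4, 3)))
        flags = np.array([1.0, 0.0, 1.0, 1.0])
        centers, means = donor_character(states, flags, energy_bins=np.array([-0.5, 0.5, 2.0, 6.0]))
        np.testing.assert_allclose(means, [1.0, 0.5, 1.0])


class TestIpr:
    def test_localized_state_is_one(self):
        states = diagonalize(np.diag([0.0, 10.0]), np.ones((2, 3)))
        np.testing.assert_allclose(ipr(states), 1.0, atol=1e-12)

    def test_uniform_state_is_n(self):
        n = 10
        states = diagonalize(ring_hamiltonian(n), np.ones((n, 3)))
        k = int(np.argmin(np.abs(states.energies - states.energies.min())))
        assert ipr(states)[k] == pytest.approx(n, rel=1e-9)

    def test_bounds_in_one_to_n(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((25, 25))
        p = ipr(diagonalize(A + A.T, rng.standard_normal((25, 3))))
        assert np.all(p >= 1.0 - 1e-9) and np.all(p <= 25.0 + 1e-9)

    def test_porter_thomas_mean_n_over_three(self):
        """Random orthonormal vectors: mean participation ~ N/3 (sampling oracle)."""
        rng = np.random.default_rng(3)
        n = 200
        A = rng.standard_normal((n, n))
        Q, _ = np.linalg.qr(A)
        p = 1.0 / (Q**4).sum(axis=0)
        assert p.mean() == pytest.approx(n / 3.0, rel=0.05)

    def test_window_query_averages(self):
        states = diagonalize(np.diag([0.0, 100.0, 200.0]), np.ones((3, 3)))
        assert ipr(states, frequency_window=(-10.0, 150.0)) == pytest.approx(1.0)


class TestSuperradiance:
    def test_ring_bright_ratio_sqrt_n(self):
        n = 9
        mu = np.tile([0.0, 0.0, 1.5], (n, 1))
        states = diagonalize(ring_hamiltonian(n), mu)
        h = superradiance_histogram(states, 1.5)
        assert h["max_ratio"] == pytest.approx(np.sqrt(n), rel=1e-9)

    def test_antisymmetric_dimer_dark(self):
        H = np.array([[0.0, -50.0], [-50.0, 0.0]])
        mu = np.tile([0.0, 0.0, 1.0], (2, 1))
        states = diagonalize(H, mu)
        ratios = np.linalg.norm(states.state_dipoles, axis=1)
        assert min(ratios) == pytest.approx(0.0, abs=1e-12)

    def test_zero_site_dipole_rejected(self):
        states = diagonalize(ring_hamiltonian(3), np.ones((3, 3)))
        with pytest.raises(ValueError, match="mu_site"):
            superradiance_histogram(states, 0.0)


class TestBinnedProfile:
    def test_counts_and_means(self):
        e = np.array([0.0, 10.0, 60.0, 70.0, 80.0])
        v = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        centers, means, counts = binned_profile(e, v, bin_width=50.0)
        assert counts[0] == 2 and means[0] == pytest.approx(2.0)
        assert counts[1] == 3 and means[1] == pytest.approx(7.0)


class TestEdl:
    def test_vertical_slice_worked_number(self):
        assert round(edl_from_2d(1350.0, 350.0)) == 6

    def test_pump_probe_worked_number(self):
        assert round(edl_from_2d(1350.0, 550.0)) == 5

    def test_inverse_worked_number(self):
        """Per-bond coupling needed for EDL = 200 at a 350 cm^-1 shift."""
        out = coupling_for_edl(200.0, 350.0)
        assert out["effective_bond_coupling"] == pytest.approx(455_000.0, rel=0.06)

    def test_forward_inverse_round_trip(self):
        S = coupling_for_edl(37.0, 120.0)["coupling_strength"]
        assert edl_from_2d(S, 120.0) == pytest.approx(37.0, rel=1e-9)

    def test_monotone_decreasing_in_blue_shift(self):
        vals = [edl_from_2d(1350.0, dw) for dw in (200.0, 350.0, 500.0, 700.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_dimer_limit(self):
        # blue shift at the dimer value of the chain factor -> EDL ~ 1
        assert edl_from_2d(1000.0, 1000.0) == pytest.approx(1.0, abs=0.3)

    @pytest.mark.parametrize("S,dw", [(0.0, 100.0), (100.0, 0.0)])
    def test_invalid_inputs(self, S, dw):
        with pytest.raises(ValueError):
            edl_from_2d(S, dw)

    def test_inverse_zero_shift_rejected(self):
        with pytest.raises(ValueError, match="blue shift"):
            coupling_for_edl(10.0, 0.0)


@pytest.fixture(scope="module")
def snapshot(middle_subsystem):
    from chlorosim.disorder import DisorderSpec, emit_trajectory
    from chlorosim.hamiltonian import assemble

    sub = middle_subsystem.subset(np.abs(middle_subsystem.positions[:, 2]) < 9.0)
    traj = emit_trajectory(sub, DisorderSpec(seed=1, n_frames=1), 1)
    H = assemble(traj, sub)
    return sub, diagonalize(H.hamiltonian_frame(0), H.dipole_vectors[0])


class TestDisorderedTubeStatistics:
    """State-level statistics of one calibrated disordered snapshot."""

    def test_oscillator_strength_at_band_bottom(self, snapshot):
        _, states = snapshot
        f = oscillator_strengths(states)
        order = np.argsort(states.energies)
        dec = max(int(0.1 * states.n), 1)
        assert f[order[:dec]].sum() / f.sum() > 0.5

    def test_ipr_maximal_mid_band(self, snapshot):
        """IPR vs energy rises from the band edges to an interior maximum."""
        _, states = snapshot
        centers, means, counts = binned_profile(states.energies, ipr(states), 300.0)
        ok = counts >= 5  # skip sparsely populated tail bins
        means, centers = means[ok], centers[ok]
        k = int(np.nanargmax(means))
        assert 0 < k < len(means) - 1
        assert means[k] > 2.0 * means[0]
        assert means[k] > 2.0 * means[-1]

    def test_donor_character_rises_across_band(self, snapshot):
        sub, states = snapshot
        e = states.energies
        edges = np.quantile(e, np.linspace(0, 1, 5))
        edges[-1] += 1.0
        _, means = donor_character(states, sub.donor.astype(float), edges)
        assert np.all(np.diff(means) > 0)
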