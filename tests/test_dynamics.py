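import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnafret.dyes import DipoleInstance
from dnafret.dynamics import (
    decay_associated_spectra,
    integrated_populations,
    kmc_transfer_efficiency,
    solve_transient,
    transfer_efficiency,
)
from dnafret.photophysics import RateMatrix, build_rate_matrix

from conftest import make_species


def _two_dye_K(r, R0=5.0, species=None, tau_d=1.0, tau_a=2.0):
    species = species or {
        "D": make_species("D", 350, 420, lifetime_ns=tau_d),
        "A": make_species("A", 650, 720, lifetime_ns=tau_a),
    }
    dips = [
        DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
        DipoleInstance([r, 0, 0], [0, 0, 1], "A"),
    ]
    return build_rate_matrix(
        dips, species, r0_overrides={("D", "A"): R0}, acceptor_ids=(1,)
    )


class TestSolveTransient:
    def test_single_dye_scalar_decay(self):
        sp = make_species("D", 400, 450, lifetime_ns=1.0)
        K = build_rate_matrix([DipoleInstance([0, 0, 0], [0, 0, 1], "D")], {"D": sp})
        state = solve_transient(K, [1.0], np.array([0.5, 1.0, 2.0]))
        assert state.populations[0] == pytest.approx(
            np.exp(-np.array([0.5, 1.0, 2.0])), rel=1e-10
        )
        assert state.populations[0, 1] == pytest.approx(0.3679, abs=1e-4)

    def test_two_dye_matches_hand_solved_biexponential(self):
        # K = [[-a, 0], [k, -b]]: p1 = e^{-at}, p2 = k(e^{-bt}-e^{-at})/(a-b)
        K = _two_dye_K(5.0)
        a, k, b = -K.K[0, 0], K.K[1, 0], -K.K[1, 1]
        t = np.linspace(0.1, 8.0, 40)
        state = solve_transient(K, [1.0, 0.0], t)
        assert np.allclose(state.populations[0], np.exp(-a * t), atol=1e-10)
        assert np.allclose(
            state.populations[1],
            k * (np.exp(-b * t) - np.exp(-a * t)) / (a - b),
            atol=1e-10,
        )

    def test_total_population_decays_monotonically(self):
        K = _two_dye_K(3.0)
        t = np.linspace(0.01, 10.0, 200)
        total = solve_transient(K, [0.5, 0.5], t).total()
        assert total[0] <= 1.0 + 1e-12
        assert np.all(np.diff(total) <= 1e-12)
        assert np.all(solve_transient(K, [0.5, 0.5], t).populations >= 0)

    def test_input_validation(self):
        K = _two_dye_K(3.0)
        with pytest.raises(ValueError):
            solve_transient(K, [0.7, 0.7], [1.0])  # p0 not normalized
        with pytest.raises(ValueError):
            solve_transient(K, [1.0, 0.0], [2.0, 1.0])  # non-increasing times


class TestIntegratedPopulations:
    def test_single_dye_integral_is_lifetime(self):
        sp = make_species("D", 400, 450, lifetime_ns=3.7)
        K = build_rate_matrix([DipoleInstance([0, 0, 0], [0, 0, 1], "D")], {"D": sp})
        assert integrated_populations(K, [1.0])[0] == pytest.approx(3.7, rel=1e-12)

    def test_agrees_with_time_quadrature_of_transient(self):
        K = _two_dye_K(5.0)
        x = integrated_populations(K, [1.0, 0.0])
        t = np.linspace(0.0, 50.0 * 2.0, 200001)
        state = solve_transient(K, [1.0, 0.0], t[1:])
        p = np.hstack([np.array([[1.0], [0.0]]), state.populations])
        quad = np.trapezoid(p, t, axis=1)
        assert np.allclose(quad, x, rtol=1e-6)

    def test_linearity_in_initial_condition(self):
        K = _two_dye_K(4.0)
        xa = integrated_populations(K, [1.0, 0.0])
        xb = integrated_populations(K, [0.0, 1.0])
        xm = integrated_populations(K, [0.5, 0.5])
        assert np.allclose(0.5 * xa + 0.5 * xb, xm, atol=1e-14)


class TestTransferEfficiency:
    def test_half_at_forster_distance(self):
        K = _two_dye_K(5.0, R0=5.0)
        assert transfer_efficiency(K, [1.0, 0.0]) == pytest.approx(0.5, abs=1e-10)

    def test_everything_recombines_somewhere(self):
        K = _two_dye_K(3.5)
        T = transfer_efficiency(K, [1.0, 0.0], acceptor_ids=(0, 1))
        assert T == pytest.approx(1.0, abs=1e-12)

    def test_acceptor_plus_nonacceptor_fractions_sum_to_one(self):
        K = _two_dye_K(4.2)
        x = integrated_populations(K, [1.0, 0.0])
        T = transfer_efficiency(K, [1.0, 0.0])
        lost_at_donor = x[0] / K.lifetimes[0]
        assert T + lost_at_donor == pytest.approx(1.0, abs=1e-10)

    def test_three_dye_chain_matches_path_enumeration(self, disjoint_chain):
        # no back transfer: T = P(d->b)P(b->a) + P(d->a), with branch
        # probabilities k / (sum of outgoing rates + 1/tau)
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
            DipoleInstance([3.0, 0, 0], [0, 0, 1], "B"),
            DipoleInstance([6.0, 0, 0], [0, 0, 1], "A"),
        ]
        overrides = {("D", "B"): 4.0, ("B", "A"): 4.5, ("D", "A"): 3.0}
        K = build_rate_matrix(
            dips, disjoint_chain, r0_overrides=overrides, acceptor_ids=(2,)
        )
        k_db, k_da, k_ba = K.K[1, 0], K.K[2, 0], K.K[2, 1]
        tau = K.lifetimes
        p_db = k_db / (k_db + k_da + 1.0 / tau[0])
        p_da = k_da / (k_db + k_da + 1.0 / tau[0])
        p_ba = k_ba / (k_ba + 1.0 / tau[1])
        expected = p_db * p_ba + p_da
        assert transfer_efficiency(K, [1.0, 0.0, 0.0]) == pytest.approx(
            expected, abs=1e-10
        )

    def test_unknown_or_empty_acceptors_rejected(self):
        K = _two_dye_K(4.0)
        with pytest.raises(ValueError):
            transfer_efficiency(K, [1.0, 0.0], acceptor_ids=())
        with pytest.raises(ValueError):
            transfer_efficiency(K, [1.0, 0.0], acceptor_ids=(5,))


class TestKineticMonteCarlo:
    def test_two_dye_at_forster_distance(self):
        K = _two_dye_K(5.0, R0=5.0)
        t_hat, se = kmc_transfer_efficiency(K, [1.0, 0.0], n_traj=2 * 10**4, seed=3)
        assert abs(t_hat - 0.5) < 3 * se

    def test_single_dye_degenerate_chain(self):
        sp = make_species("D", 400, 450)
        K = build_rate_matrix(
            [DipoleInstance([0, 0, 0], [0, 0, 1], "D")], {"D": sp}, acceptor_ids=(0,)
        )
        t_hat, _ = kmc_transfer_efficiency(K, [1.0], n_traj=500, seed=0)
        assert t_hat == 1.0

    def test_random_network_agrees_with_linear_solver(self):
        rng = np.random.default_rng(12)
        n = 6
        pos = rng.uniform(0, 6.0, size=(n, 3))
        sp = make_species("X", 500, 515, lifetime_ns=1.5)
        dips = [DipoleInstance(p, [0, 0, 1], "X") for p in pos]
        K = build_rate_matrix(dips, {"X": sp}, acceptor_ids=(n - 1,))
        p0 = np.zeros(n)
        p0[0] = 1.0
        T = transfer_efficiency(K, p0)
        t_hat, se = kmc_transfer_efficiency(K, p0, n_traj=3 * 10**4, seed=9)
        assert abs(t_hat - T) < 3 * se

    def test_deterministic_under_seed(self):
        K = _two_dye_K(5.0)
        a = kmc_transfer_efficiency(K, [1.0, 0.0], n_traj=2000, seed=5)
        b = kmc_transfer_efficiency(K, [1.0, 0.0], n_traj=2000, seed=5)
        assert a == b


class TestDecayAssociatedSpectra:
    def test_single_dye_single_component(self):
        sp = make_species("D", 400, 450, lifetime_ns=2.5)
        K = build_rate_matrix([DipoleInstance([0, 0, 0], [0, 0, 1], "D")], {"D": sp})
        das = decay_associated_spectra(K, [1.0])
        assert len(das) == 1
        assert das[0].lifetime_ns == pytest.approx(2.5, rel=1e-12)
        assert das[0].amplitude * das[0].eigenvector[0] == pytest.approx(1.0)

    def test_modes_reconstruct_initial_condition(self):
        K = _two_dye_K(4.0)
        p0 = np.array([0.7, 0.3])
        das = decay_associated_spectra(K, p0)
        recon = sum(c.amplitude * c.eigenvector for c in das)
        assert np.allclose(recon, p0, atol=1e-9)

    def test_two_dye_lifetimes_match_characteristic_roots(self):
        # 2x2 K eigenvalues from the quadratic formula
        K = _two_dye_K(4.0)
        tr = np.trace(K.K)
        det = np.linalg.det(K.K)
        roots = np.sort(
            [(tr + np.sqrt(tr**2 - 4 * det)) / 2, (tr - np.sqrt(tr**2 - 4 * det)) / 2]
        )
        das = decay_associated_spectra(K, [1.0, 0.0])
        eigs = np.sort([c.eigenvalue for c in das])
        assert np.allclose(eigs, roots, rtol=1e-10)

    def test_das_reconstruction_matches_transient_solution(self):
        K = _two_dye_K(3.5)
        p0 = np.array([0.6, 0.4])
        das = decay_associated_spectra(K, p0)
        t = np.linspace(0.05, 6.0, 30)
        recon = sum(
            c.amplitude * np.outer(c.eigenvector, np.exp(c.eigenvalue * t))
            for c in das
        )
        state = solve_transient(K, p0, t)
        assert np.allclose(recon, state.populations, atol=1e-8)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10**6))
def test_conservation_properties_on_random_networks(seed):
    """Column sums, population positivity, monotone total decay and the
    exhaustive-recombination identity hold for arbitrary geometries."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 7))
    # keep separations above the ~1 nm weak-coupling floor where the
    # Foerster model (and the solve's conditioning) is meaningful
    while True:
        pos = rng.uniform(0, 8.0, size=(n, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if np.all(d[np.triu_indices(n, 1)] > 1.0):
            break
    sp = make_species("X", 500, 512, lifetime_ns=float(rng.uniform(0.5, 4.0)))
    dips = [DipoleInstance(p, [0, 0, 1], "X") for p in pos]
    K = build_rate_matrix(dips, {"X": sp}, acceptor_ids=(0,))
    assert np.allclose(K.K.sum(axis=0), -1.0 / K.lifetimes, atol=1e-12)
    p0 = np.zeros(n)
    p0[int(rng.integers(0, n))] = 1.0
    x = integrated_populations(K, p0)
    assert np.all(x >= 0)
    recombined = x / K.lifetimes
    assert recombined.sum() == pytest.approx(1.0, abs=1e-10)
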