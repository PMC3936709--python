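import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnafret.dyes import DipoleInstance
from dnafret.photophysics import (
    FORSTER_CONSTANT_NM,
    Spectrum,
    build_rate_matrix,
    forster_radius,
    gaussian_spectrum,
    kappa_squared,
    pairwise_rate,
    spectral_overlap,
)

from conftest import make_species


class TestSpectralOverlap:
    def test_disjoint_spectra_give_zero(self):
        donor = make_species("D", 300, 350)
        acceptor = make_species("A", 650, 700)
        assert spectral_overlap(donor, acceptor) == 0.0

    def test_narrow_donor_sifts_acceptor_extinction(self):
        # delta-like donor emission at l0: J -> eps_A(l0) * l0^4
        from dnafret.photophysics import DyeSpecies

        l0 = 550.0
        donor = DyeSpecies(
            "D",
            gaussian_spectrum(400, 15, 1e5, span=3.0),
            gaussian_spectrum(l0, 0.1, 1.0, span=3.0, step=0.01),
            quantum_yield=0.9,
            lifetime_ns=1.0,
        )
        acceptor = make_species("A", 545, 650, sigma=20.0, eps_max=150000)
        J = spectral_overlap(donor, acceptor)
        expected = acceptor.absorption.value_at(l0) * l0**4
        assert J == pytest.approx(expected, rel=1e-3)

    def test_gaussian_pair_matches_fine_riemann_oracle(self):
        donor = make_species("D", 470, 520, sigma=15.0)
        acceptor = make_species("A", 550, 600, sigma=20.0, eps_max=150000)
        J = spectral_overlap(donor, acceptor)
        # independent oracle: 0.01 nm Riemann sum over analytic band shapes
        grid = np.arange(440.0, 620.0, 0.01)
        f = np.exp(-0.5 * ((grid - 520.0) / 15.0) ** 2)
        f[np.abs(grid - 520.0) > 45.0] = 0.0
        f /= np.sum(f) * 0.01
        eps = 150000 * np.exp(-0.5 * ((grid - 550.0) / 20.0) ** 2)
        eps[np.abs(grid - 550.0) > 60.0] = 0.0
        oracle = np.sum(f * eps * grid**4) * 0.01
        assert J == pytest.approx(oracle, rel=1e-3)

    def test_zero_area_emission_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([500.0, 510.0]), np.array([0.0, 0.0])).normalized()


class TestForsterRadius:
    def test_zero_overlap_gives_zero(self):
        assert forster_radius(0.0, 0.9) == 0.0

    def test_kappa_squared_sixth_root_scaling(self):
        r1 = forster_radius(5e15, 0.9, kappa2=2.0 / 3.0)
        r2 = forster_radius(5e15, 0.9, kappa2=4.0 / 3.0)
        assert r2 / r1 == pytest.approx(2.0 ** (1.0 / 6.0), rel=1e-12)

    def test_longhand_evaluation(self):
        # independent arithmetic: R0 = 0.02108 (k2 n^-4 Q J)^(1/6)
        J, Q, n = 5.0e15, 0.9, 1.33
        expected = 0.02108 * (2.0 / 3.0 * n**-4 * Q * J) ** (1.0 / 6.0)
        assert forster_radius(J, Q, 2.0 / 3.0, n) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.62, abs=0.01)

    def test_prefactor_matches_standard_tabulated_form(self):
        # the widely tabulated convention R0[A]^6 = 8.79e-5 (k2 n^-4 Q J)
        # with J in M^-1 cm^-1 nm^4 implies R0[nm]^6 = 8.79e-11 (...)
        assert FORSTER_CONSTANT_NM**6 == pytest.approx(8.79e-11, rel=5e-3)


class TestKappaSquared:
    def test_collinear_head_to_tail_is_four(self):
        assert kappa_squared([0, 0, 1], [0, 0, 1], [0, 0, 3.0]) == pytest.approx(4.0)

    def test_parallel_perpendicular_to_r_is_one(self):
        assert kappa_squared([1, 0, 0], [1, 0, 0], [0, 0, 3.0]) == pytest.approx(1.0)

    def test_orthogonal_with_one_along_r_is_zero(self):
        assert kappa_squared([0, 0, 1], [1, 0, 0], [0, 0, 3.0]) == pytest.approx(0.0)

    def test_zero_separation_is_singular(self):
        with pytest.raises(ValueError):
            kappa_squared([0, 0, 1], [0, 0, 1], [0, 0, 0])

    def test_isotropic_monte_carlo_average_two_thirds(self):
        rng = np.random.default_rng(0)
        n = 10**5
        mu = rng.normal(size=(2, n, 3))
        mu /= np.linalg.norm(mu, axis=-1, keepdims=True)
        r_hat = np.array([0.0, 0.0, 1.0])
        k = (mu[0] * mu[1]).sum(axis=1) - 3.0 * (mu[0] @ r_hat) * (mu[1] @ r_hat)
        k2 = k**2
        se = k2.std(ddof=1) / math.sqrt(n)
        assert abs(k2.mean() - 2.0 / 3.0) < 3 * se

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10**6))
    def test_kappa_squared_bounded(self, seed):
        rng = np.random.default_rng(seed)
        mu_i, mu_j, r = rng.normal(size=(3, 3))
        if np.linalg.norm(r) < 1e-12:
            return
        k2 = kappa_squared(
            mu_i / np.linalg.norm(mu_i), mu_j / np.linalg.norm(mu_j), r
        )
        assert -1e-12 <= k2 <= 4.0 + 1e-12


class TestPairwiseRate:
    def test_definition_point(self):
        donor = make_species("D", 400, 450, lifetime_ns=1.0)
        assert pairwise_rate(donor, R0_iso=5.0, r=5.0) == pytest.approx(1.0, abs=1e-12)

    def test_sixth_power_law(self):
        donor = make_species("D", 400, 450, lifetime_ns=2.0)
        assert pairwise_rate(donor, 5.0, 2.5) == pytest.approx(64.0 / 2.0, rel=1e-12)

    def test_af488_cy5_ten_bp_efficiency_closed_form(self):
        # printed R0 5.2 nm and 0.34 nm/bp rise: E = 1/(1+(3.4/5.2)^6)
        donor = make_species("D", 490, 520, lifetime_ns=1.0)
        r = 10 * 0.34
        k = pairwise_rate(donor, 5.2, r)
        assert k / (k + 1.0) == pytest.approx(1.0 / (1.0 + (3.4 / 5.2) ** 6), rel=1e-12)
        assert k / (k + 1.0) == pytest.approx(0.9275, abs=5e-4)

    def test_explicit_kappa_scales_by_three_halves(self):
        donor = make_species("D", 400, 450, lifetime_ns=1.0)
        base = pairwise_rate(donor, 5.0, 4.0)
        assert pairwise_rate(donor, 5.0, 4.0, kappa2=2.0 / 3.0) == pytest.approx(base)
        assert pairwise_rate(donor, 5.0, 4.0, kappa2=4.0) == pytest.approx(6.0 * base)


class TestRateMatrix:
    def test_single_dye_matrix(self):
        sp = make_species("D", 400, 450, lifetime_ns=2.0)
        K = build_rate_matrix(
            [DipoleInstance([0, 0, 0], [0, 0, 1], "D")], {"D": sp}
        )
        assert np.allclose(K.K, [[-0.5]])

    def test_homo_fret_is_symmetric(self):
        sp = make_species("D", 500, 510, lifetime_ns=1.0)
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
            DipoleInstance([3.0, 0, 0], [0, 0, 1], "D"),
        ]
        K = build_rate_matrix(dips, {"D": sp})
        assert K.K[0, 1] == pytest.approx(K.K[1, 0], rel=1e-12)
        assert K.K[0, 1] > 0

    def test_column_sums_close_to_minus_inverse_lifetime(self):
        table = {
            "D": make_species("D", 450, 500, lifetime_ns=1.3),
            "B": make_species("B", 495, 545, lifetime_ns=0.7),
            "A": make_species("A", 540, 590, lifetime_ns=2.1),
        }
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
            DipoleInstance([2.5, 0, 0], [0, 1, 0], "B"),
            DipoleInstance([5.0, 1.0, 0], [1, 0, 0], "A"),
        ]
        for mode in ("dynamic", "static"):
            K = build_rate_matrix(dips, table, mode=mode)
            colsums = K.K.sum(axis=0)
            assert np.allclose(colsums, -1.0 / K.lifetimes, atol=1e-12)

    def test_rate_asymmetry_follows_quantum_yield_and_overlap(self):
        # k_ij / k_ji = (Q_i J_ij / tau_i) / (Q_j J_ji / tau_j)
        sp_i = make_species("I", 490, 530, quantum_yield=0.8, lifetime_ns=1.0)
        sp_j = make_species("J", 520, 560, quantum_yield=0.3, lifetime_ns=2.0)
        table = {"I": sp_i, "J": sp_j}
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "I"),
            DipoleInstance([3.0, 0, 0], [0, 0, 1], "J"),
        ]
        K = build_rate_matrix(dips, table)
        expected = (
            0.8 * spectral_overlap(sp_i, sp_j) / 1.0
        ) / (0.3 * spectral_overlap(sp_j, sp_i) / 2.0)
        assert K.K[1, 0] / K.K[0, 1] == pytest.approx(expected, rel=1e-9)

    def test_coincident_dipoles_rejected(self):
        sp = make_species("D", 500, 510)
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
            DipoleInstance([0, 0, 0], [1, 0, 0], "D"),
        ]
        with pytest.raises(ValueError, match="coincident"):
            build_rate_matrix(dips, {"D": sp})

    def test_r0_override_bypasses_spectra(self):
        sp = {"D": make_species("D", 350, 400, lifetime_ns=1.0),
              "A": make_species("A", 650, 700)}
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
            DipoleInstance([5.0, 0, 0], [0, 0, 1], "A"),
        ]
        K = build_rate_matrix(dips, sp, r0_overrides={("D", "A"): 5.0})
        assert K.K[1, 0] == pytest.approx(1.0, rel=1e-12)
        assert K.K[0, 1] == 0.0  # disjoint spectra: no back transfer


def test_forster_radius_consistent_on_finer_grid():
    # R0 from the default union-grid quadrature agrees with a 10x finer
    # resampled evaluation to 0.5%
    donor = make_species("D", 470, 520, sigma=15.0)
    acceptor = make_species("A", 550, 600, sigma=20.0, eps_max=150000)
    J = spectral_overlap(donor, acceptor)
    grid = np.arange(445.0, 612.0, 0.1)
    f = donor.emission.value_at(grid)
    f = f / np.trapezoid(donor.emission.value_at(np.arange(475.0, 565.01, 0.1)),
                         np.arange(475.0, 565.01, 0.1))
    eps = acceptor.absorption.value_at(grid)
    J_fine = np.trapezoid(f * eps * grid**4, grid)
    r0 = forster_radius(J, 0.9)
    r0_fine = forster_radius(J_fine, 0.9)
    assert r0 == pytest.approx(r0_fine, rel=5e-3)


def test_density_dependent_photophysics_interpolates():
    sp = make_species("YO", 491, 509)
    sp = sp.__class__(
        sp.name, sp.absorption, sp.emission, 0.5, 2.0,
        density_table=((0.0, 0.5), (0.5, 0.3), (2.0, 1.0)),
    )
    mid = sp.at_density(0.25)
    assert mid.quantum_yield == pytest.approx(0.4)
    assert mid.lifetime_ns == pytest.approx(1.5)
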