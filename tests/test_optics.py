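import numpy as np
import pytest

from dnafret.dyes import DipoleInstance
from dnafret.dynamics import integrated_populations
from dnafret.optics import (
    antenna_effect,
    assembly_absorption_spectrum,
    assembly_emission_spectrum,
    energy_transfer_efficiency,
    extinction_to_cross_section_cm2,
    initial_excitation,
    reference_solar_irradiance,
    transfer_efficiency_spectrum,
    transferred_power,
)
from dnafret.photophysics import Spectrum, build_rate_matrix

from conftest import make_species


class TestInitialExcitation:
    def test_single_dye_fully_excited(self):
        sp = make_species("D", 500, 550)
        assert initial_excitation([sp], 500.0) == pytest.approx([1.0])

    def test_identical_dyes_split_evenly(self):
        sp = make_species("D", 500, 550)
        assert np.allclose(initial_excitation([sp, sp], 505.0), [0.5, 0.5])

    def test_extinction_ratio_three_to_one(self):
        a = make_species("A", 500, 550, eps_max=3e5)
        b = make_species("B", 500, 560, eps_max=1e5)
        assert np.allclose(initial_excitation([a, b], 500.0), [0.75, 0.25])

    def test_no_absorption_raises(self):
        sp = make_species("D", 500, 550)
        with pytest.raises(ValueError, match="no dye absorbs"):
            initial_excitation([sp], 800.0)


class TestAbsorption:
    def test_n_identical_dyes_scale_linearly(self):
        sp = make_species("D", 500, 550, eps_max=1e5)
        total = assembly_absorption_spectrum([sp] * 4)
        assert total.value_at(500.0) == pytest.approx(4e5, rel=1e-9)

    def test_cross_section_unit_conversion(self):
        # eps = 1e5 M^-1 cm^-1 -> sigma = ln10 * 1e3 * 1e5 / N_A cm^2
        sigma = extinction_to_cross_section_cm2(1e5)
        assert sigma == pytest.approx(3.82e-16, rel=1e-3)

    def test_disjoint_supports_sum_piecewise_without_nans(self):
        a = make_species("A", 400, 450)
        b = make_species("B", 650, 700)
        total = assembly_absorption_spectrum([a, b])
        assert np.all(np.isfinite(total.values))
        assert total.value_at(400.0) == pytest.approx(1e5, rel=1e-9)
        assert total.value_at(650.0) == pytest.approx(1e5, rel=1e-9)


class TestEmission:
    def _pair_K(self, r):
        table = {
            "D": make_species("D", 350, 420, quantum_yield=0.9, lifetime_ns=1.0),
            "A": make_species("A", 650, 720, quantum_yield=0.5, lifetime_ns=2.0),
        }
        dips = [
            DipoleInstance([0, 0, 0], [0, 0, 1], "D"),
            DipoleInstance([r, 0, 0], [0, 0, 1], "A"),
        ]
        return build_rate_matrix(
            dips, table, r0_overrides={("D", "A"): 5.0}, acceptor_ids=(1,)
        )

    def test_single_dye_emits_its_own_spectrum_times_q(self):
        sp = make_species("D", 400, 450, quantum_yield=0.7)
        K = build_rate_matrix([DipoleInstance([0, 0, 0], [0, 0, 1], "D")], {"D": sp})
        em = assembly_emission_spectrum(K, [1.0])
        assert em.area() == pytest.approx(0.7, rel=1e-9)
        assert em.peak_wavelength() == pytest.approx(450.0, abs=1.0)

    def test_perfect_transfer_quenches_donor_emission(self):
        K = self._pair_K(1.5)  # r << R0: T -> 1
        em = assembly_emission_spectrum(K, [1.0, 0.0])
        donor_band = em.value_at(420.0)
        acceptor_band = em.value_at(720.0)
        assert donor_band < 0.01 * acceptor_band

    def test_total_emitted_quanta_bounded_by_one(self):
        for r in (1.5, 4.0, 8.0):
            K = self._pair_K(r)
            em = assembly_emission_spectrum(K, [1.0, 0.0])
            x = integrated_populations(K, [1.0, 0.0])
            quanta = sum(
                s.quantum_yield / s.lifetime_ns * xi for s, xi in zip(K.species, x)
            )
            assert em.area() == pytest.approx(quanta, rel=1e-9)
            assert quanta <= 1.0 + 1e-12

    def test_sigma_eff_below_sigma_pointwise(self):
        K = self._pair_K(4.0)
        wl = np.arange(320.0, 700.0, 5.0)
        T_spec = transfer_efficiency_spectrum(K, wl)
        assert np.all(T_spec.values <= 1.0 + 1e-12)
        assert np.all(T_spec.values >= 0.0)
        sigma = extinction_to_cross_section_cm2(
            assembly_absorption_spectrum(K.species).value_at(wl)
        )
        assert np.all(sigma * T_spec.values <= sigma + 1e-30)


class TestTransferredPower:
    def test_zero_irradiance_gives_zero(self):
        sigma = Spectrum(np.array([400.0, 700.0]), np.array([1e-16, 1e-16]))
        dark = Spectrum(np.array([400.0, 700.0]), np.array([0.0, 0.0]))
        assert transferred_power(sigma, dark, 1.0) == 0.0

    def test_boxcar_closed_form(self):
        # flat sigma_eff over [400, 700] nm under flat irradiance:
        # P = T_E * I0 * sigma * (300 nm), with cm^2 -> m^2
        wl = np.linspace(400.0, 700.0, 301)
        sigma = Spectrum(wl, np.full_like(wl, 2e-16))
        irr = Spectrum(wl, np.full_like(wl, 1.5))
        P = transferred_power(sigma, irr, T_E=0.8)
        assert P == pytest.approx(0.8 * 1.5 * 2e-16 * 1e-4 * 300.0, rel=1e-3)

    def test_linearity_in_irradiance(self):
        wl = np.linspace(400.0, 700.0, 100)
        sigma = Spectrum(wl, 1e-16 * np.exp(-((wl - 550) / 60.0) ** 2))
        irr = Spectrum(wl, np.exp(-((wl - 500) / 90.0) ** 2))
        doubled = Spectrum(wl, 2 * irr.values)
        assert transferred_power(sigma, doubled) == pytest.approx(
            2 * transferred_power(sigma, irr), rel=1e-12
        )

    def test_disjoint_grids_give_zero(self):
        sigma = Spectrum(np.array([400.0, 450.0]), np.array([1e-16, 1e-16]))
        irr = Spectrum(np.array([600.0, 700.0]), np.array([1.0, 1.0]))
        assert transferred_power(sigma, irr) == 0.0


class TestEnergyEfficiencyAndAntennaEffect:
    def test_identical_dyes_energy_ratio_one(self):
        sp = make_species("D", 500, 550)
        assert energy_transfer_efficiency(0.7, sp, sp) == pytest.approx(0.7)

    def test_peak_wavelength_ratio(self):
        d = make_species("D", 480, 520)
        a = make_species("A", 600, 650)
        assert energy_transfer_efficiency(0.9, d, a) == pytest.approx(
            0.9 * 520.0 / 650.0, rel=1e-9
        )

    def test_zero_transfer_gives_zero(self):
        d = make_species("D", 480, 520)
        a = make_species("A", 600, 650)
        assert energy_transfer_efficiency(0.0, d, a) == 0.0

    def test_unit_case(self):
        assert antenna_effect(1, 1e5, 1e5, 1.0) == pytest.approx(1.0)

    def test_linear_in_donor_count_and_transfer(self):
        base = antenna_effect(1, 5e4, 2e5, 0.5)
        assert antenna_effect(6, 5e4, 2e5, 0.5) == pytest.approx(6 * base, rel=1e-12)
        assert antenna_effect(1, 5e4, 2e5, 1.0) == pytest.approx(2 * base, rel=1e-12)

    def test_zero_acceptor_extinction_rejected(self):
        with pytest.raises(ValueError):
            antenna_effect(1, 1e5, 0.0, 0.5)


def test_reference_solar_irradiance_is_smooth_and_scaled():
    irr = reference_solar_irradiance()
    assert np.all(irr.values >= 0)
    # visible-band magnitude of order 1 W m^-2 nm^-1
    assert 0.5 < irr.value_at(550.0) < 3.0
    # peak in the visible
    assert 400.0 < irr.peak_wavelength() < 650.0
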