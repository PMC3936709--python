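"""Assembly-level optical properties and light-harvesting metrics.

From the rate matrix and the dye spectra this module derives the
quantities a light-harvesting designer optimizes: the wavelength-resolved
transfer efficiency T(lambda), the assembly absorption spectrum and
cross-section sigma(lambda), the effective cross-section
sigma_eff = sigma * T, the power transferred to the acceptors under a
given irradiance,

    P = T_E * int I(lambda) sigma(lambda) T(lambda) dlambda,

and the antenna effect

    AE = T * n_D eps_D(lambda_exc) / eps_A(lambda_A),

the ratio of acceptor fluorescence under donor excitation to direct
acceptor excitation at equal photon intensity.  T_E converts the exciton
count efficiency into an energy efficiency via the donor/acceptor
emission photon-energy ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .photophysics import DyeSpecies, RateMatrix, Spectrum
from .dynamics import integrated_populations, transfer_efficiency

__all__ = [
    "AVOGADRO",
    "LightHarvestingReport",
    "initial_excitation",
    "assembly_absorption_spectrum",
    "extinction_to_cross_section_cm2",
    "assembly_emission_spectrum",
    "transfer_efficiency_spectrum",
    "energy_transfer_efficiency",
    "transferred_power",
    "antenna_effect",
    "reference_solar_irradiance",
    "light_harvesting_report",
]

log = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23


def initial_excitation(species: list[DyeSpecies], wavelength: float) -> np.ndarray:
    """Initial exciton distribution p0 at an excitation wavelength:
    each dye is excited in proportion to its molar extinction there."""
    eps = np.array([s.absorption.value_at(wavelength) for s in species], dtype=float)
    total = eps.sum()
    if total <= 0:
        raise ValueError(f"no dye absorbs at {wavelength} nm")
    return eps / total


def extinction_to_cross_section_cm2(extinction) -> np.ndarray:
    """Molar extinction [M^-1 cm^-1] -> absorption cross-section [cm^2]:
    sigma = 1000 ln(10) eps / N_A."""
    return 1000.0 * np.log(10.0) * np.asarray(extinction, dtype=float) / AVOGADRO


def assembly_absorption_spectrum(species: list[DyeSpecies]) -> Spectrum:
    """Total molar extinction of the assembly: sum of the per-dye spectra on
    their union wavelength grid (linear in the number of absorbing dyes)."""
    if not species:
        raise ValueError("need at least one dye")
    grid = np.unique(np.concatenate([s.absorption.wavelengths for s in species]))
    total = np.zeros_like(grid)
    for s in species:
        total += s.absorption.value_at(grid)
    return Spectrum(grid, total)


def assembly_emission_spectrum(K: RateMatrix, p0) -> Spectrum:
    """Steady-state emitted-quanta spectrum: sum_i (Q_i/tau_i) int p_i dt F_i."""
    x = integrated_populations(K, p0)
    species = K.species
    grid = np.unique(np.concatenate([s.emission.wavelengths for s in species]))
    vals = np.zeros_like(grid)
    for xi, s in zip(x, species):
        vals += s.quantum_yield / s.lifetime_ns * xi * s.emission.value_at(grid)
    return Spectrum(grid, np.clip(vals, 0.0, None))


def transfer_efficiency_spectrum(K: RateMatrix, wavelengths) -> Spectrum:
    """T(lambda): transfer efficiency with the initial excitation set by the
    relative dye extinctions at each wavelength (zero where nothing absorbs)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    T = np.zeros_like(wavelengths)
    for idx, wl in enumerate(wavelengths):
        try:
            p0 = initial_excitation(K.species, wl)
        except ValueError:
            continue
        T[idx] = transfer_efficiency(K, p0)
    return Spectrum(wavelengths, T)


def energy_transfer_efficiency(
    T: float,
    donor: DyeSpecies,
    acceptor: DyeSpecies,
    energy_ratio: float | None = None,
) -> float:
    """Energy-weighted efficiency T_E: the exciton arriving at the acceptor
    carries less energy than the one created at the donor.  By default the
    ratio of donor/acceptor emission-peak wavelengths (photon energy ratio
    lambda_D / lambda_A) converts counts to energy; pass ``energy_ratio``
    to override."""
    if energy_ratio is None:
        energy_ratio = donor.emission.peak_wavelength() / acceptor.emission.peak_wavelength()
    return T * energy_ratio


def transferred_power(
    sigma_eff_cm2: Spectrum, irradiance: Spectrum, T_E: float = 1.0
) -> float:
    """Power [W] transferred to the acceptors under a spectral irradiance
    [W m^-2 nm^-1]; sigma_eff in cm^2.  Trapezoidal quadrature on the
    overlap of the two grids."""
    lo = max(sigma_eff_cm2.wavelengths[0], irradiance.wavelengths[0])
    hi = min(sigma_eff_cm2.wavelengths[-1], irradiance.wavelengths[-1])
    if hi <= lo:
        log.warning("irradiance and cross-section grids do not overlap; P = 0")
        return 0.0
    grid = np.union1d(sigma_eff_cm2.wavelengths, irradiance.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    integrand = sigma_eff_cm2.value_at(grid) * 1e-4 * irradiance.value_at(grid)
    return float(T_E * np.trapezoid(integrand, grid))


def antenna_effect(
    n_donors: int, eps_donor_exc: float, eps_acceptor_readout: float, T: float
) -> float:
    """Antenna effect AE = T * n_D eps_D(lambda_exc) / eps_A(lambda_A)
    (equal photon intensity for donor and direct acceptor excitation)."""
    if eps_acceptor_readout <= 0:
        raise ValueError("acceptor extinction at the readout wavelength must be > 0")
    return T * n_donors * eps_donor_exc / eps_acceptor_readout


def reference_solar_irradiance(wavelengths=None) -> Spectrum:
    """Smooth standard-sunlight stand-in [W m^-2 nm^-1].

    A 5772 K blackbody curve scaled so the 280-2500 nm band integrates to
    1000 W m^-2 — a synthetic, structureless approximation of terrestrial
    solar irradiance suitable for relative antenna comparisons; substitute
    tabulated reference data for absolute work.
    """
    if wavelengths is None:
        wavelengths = np.arange(280.0, 1500.0 + 1, 5.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    hc_over_k = 1.43877688e7  # nm K
    T_sun = 5772.0

    def planck(wl):
        return wl**-5 / np.expm1(hc_over_k / (wl * T_sun))

    ref_grid = np.arange(280.0, 2500.0, 2.0)
    scale = 1000.0 / np.trapezoid(planck(ref_grid), ref_grid)
    return Spectrum(wavelengths, scale * planck(wavelengths))


@dataclass
class LightHarvestingReport:
    """Derived light-harvesting metrics of one assembly configuration."""

    wavelengths: np.ndarray
    transfer_efficiency: float  # T at the excitation wavelength
    energy_efficiency: float  # T_E
    T_spectrum: Spectrum
    extinction: Spectrum  # assembly molar extinction on `wavelengths`
    sigma_cm2: np.ndarray
    sigma_eff_cm2: np.ndarray
    transferred_power_w: float
    antenna_effect: float
    excitation_wavelength: float
    acceptor_readout_wavelength: float


def light_harvesting_report(
    K: RateMatrix,
    excitation_wavelength: float,
    acceptor_readout_wavelength: float,
    irradiance: Spectrum | None = None,
    wavelengths=None,
) -> LightHarvestingReport:
    """Full light-harvesting characterization of an assembly.

    Donor sites are all non-acceptor sites; the antenna effect compares
    excitation at ``excitation_wavelength`` with direct acceptor excitation
    at ``acceptor_readout_wavelength``.  T(lambda) and sigma_eff are
    evaluated on ``wavelengths`` (default: the union absorption grid).
    """
    species = K.species
    if wavelengths is None:
        wavelengths = np.unique(
            np.concatenate([s.absorption.wavelengths for s in species])
        )
    wavelengths = np.asarray(wavelengths, dtype=float)
    irradiance = irradiance if irradiance is not None else reference_solar_irradiance()

    acceptors = set(K.acceptor_ids)
    donors = [i for i in range(K.n) if i not in acceptors]
    if not donors or not acceptors:
        raise ValueError("need at least one donor and one acceptor site")

    p0_exc = initial_excitation(species, excitation_wavelength)
    T_exc = transfer_efficiency(K, p0_exc)

    T_spec = transfer_efficiency_spectrum(K, wavelengths)
    extinction = assembly_absorption_spectrum(species)
    eps_grid = extinction.value_at(wavelengths)
    sigma = extinction_to_cross_section_cm2(eps_grid)
    sigma_eff = sigma * T_spec.values

    donor_sp = species[donors[int(np.argmax([
        species[i].absorption.value_at(excitation_wavelength) for i in donors
    ]))]]
    acceptor_sp = species[next(iter(acceptors))]
    T_E = energy_transfer_efficiency(T_exc, donor_sp, acceptor_sp)

    P = transferred_power(
        Spectrum(wavelengths, np.clip(sigma_eff, 0.0, None)), irradiance, T_E
    )

    eps_donor = sum(
        species[i].absorption.value_at(excitation_wavelength) for i in donors
    ) / max(len(donors), 1)
    eps_acceptor = sum(
        species[a].absorption.value_at(acceptor_readout_wavelength) for a in acceptors
    )
    ae = antenna_effect(len(donors), eps_donor, eps_acceptor, T_exc)

    return LightHarvestingReport(
        wavelengths=wavelengths,
        transfer_efficiency=T_exc,
        energy_efficiency=T_E,
        T_spectrum=T_spec,
        extinction=Spectrum(wavelengths, eps_grid),
        sigma_cm2=sigma,
        sigma_eff_cm2=sigma_eff,
        transferred_power_w=P,
        antenna_effect=ae,
        excitation_wavelength=excitation_wavelength,
        acceptor_readout_wavelength=acceptor_readout_wavelength,
    )
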