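"""Dye photophysics and Förster-rate machinery.

Unit system: wavelengths nm, molar extinction M^-1 cm^-1, spectral
overlap J in M^-1 cm^-1 nm^4, distances nm, lifetimes ns, rates ns^-1.
The single unit-system anchor is the Förster-radius prefactor

    R0 = 0.02108 * (kappa^2 n^-4 Q_D J)^(1/6)  [nm],

i.e. (9000 ln10 / (128 pi^5 N_A))^(1/6) evaluated with J in
M^-1 cm^-1 nm^4 and R0 in nm (the familiar 0.211 Angstrom form).

The pairwise donor->acceptor transfer rate is

    k = (1/tau_D) * (3 kappa^2 / 2) * (R0_iso / r)^6,

with R0_iso the isotropic (kappa^2 = 2/3) reference radius, so that
explicit orientations enter only through the dimensionless 3 kappa^2/2.

Rate-matrix convention: K[i][j] (i != j) is the transfer rate from dye j
to dye i; the diagonal closes each column to -1/tau_j, so dp/dt = K p
conserves excitons up to recombination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dyes import DipoleInstance

__all__ = [
    "FORSTER_CONSTANT_NM",
    "Spectrum",
    "DyeSpecies",
    "RateMatrix",
    "gaussian_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "spectral_overlap",
    "forster_radius",
    "kappa_squared",
    "pairwise_rate",
    "build_rate_matrix",
]

log = logging.getLogger(__name__)

#: (9000 ln10 / (128 pi^5 N_A))^(1/6) with J in M^-1 cm^-1 nm^4, R0 in nm
FORSTER_CONSTANT_NM = 0.02108

#: separations below this are outside the weak-coupling (Foerster) regime
FORSTER_VALIDITY_FLOOR_NM = 1.0

_floor_warned = [False]


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-gridded optical curve (grid strictly increasing, values >= 0)."""

    wavelengths: np.ndarray  # nm
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.shape != vals.shape:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite entries")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectral values must be non-negative")

    def area(self) -> float:
        return float(np.trapezoid(self.values, self.wavelengths))

    def normalized(self) -> "Spectrum":
        """Unit-area version (emission spectra in quanta/nm)."""
        a = self.area()
        if a <= 0:
            raise ValueError("cannot normalize a spectrum with zero area")
        return Spectrum(self.wavelengths, self.values / a)

    def value_at(self, wavelength) -> np.ndarray | float:
        """Linear interpolation; zero outside the tabulated range."""
        return np.interp(wavelength, self.wavelengths, self.values, left=0.0, right=0.0)

    def peak_wavelength(self) -> float:
        return float(self.wavelengths[int(np.argmax(self.values))])


def gaussian_spectrum(center: float, sigma: float, peak: float,
                      span: float = 5.0, step: float = 1.0) -> Spectrum:
    """Synthetic Gaussian band: peak value at ``center`` nm, width ``sigma``,
    truncated at ``span`` sigma with explicit zero edges (so quadrature on
    union grids does not smear the band beyond its support)."""
    wl = np.arange(center - span * sigma, center + span * sigma + step / 2, step)
    vals = peak * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    wl = np.concatenate([[wl[0] - step], wl, [wl[-1] + step]])
    vals = np.concatenate([[0.0], vals, [0.0]])
    return Spectrum(wl, vals)


def read_spectrum_csv(path) -> Spectrum:
    """Two-column CSV (wavelength_nm, value) with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength_nm, value)")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spectrum_csv(spectrum: Spectrum, path, value_name: str = "value") -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, value_name: spectrum.values}
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class DyeSpecies:
    """A dye's photophysics: spectra, quantum yield and lifetime.

    ``absorption`` carries molar extinction [M^-1 cm^-1]; ``emission`` is
    normalized internally to unit area.  The optional ``density_table``
    maps intercalator binding density (dyes/bp) to (quantum_yield,
    lifetime_ns) by piecewise-linear interpolation, for dyes whose
    photophysics depends on loading.
    """

    name: str
    absorption: Spectrum
    emission: Spectrum
    quantum_yield: float
    lifetime_ns: float
    density_table: tuple | None = None  # ((density,...), (Q,...), (tau,...))

    def __post_init__(self):
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.lifetime_ns <= 0:
            raise ValueError("lifetime must be positive")
        object.__setattr__(self, "emission", self.emission.normalized())

    def at_density(self, density: float) -> "DyeSpecies":
        """Species with (Q, tau) interpolated at the given binding density."""
        if self.density_table is None:
            return self
        d, q, tau = (np.asarray(a, dtype=float) for a in self.density_table)
        return replace(
            self,
            quantum_yield=float(np.interp(density, d, q)),
            lifetime_ns=float(np.interp(density, d, tau)),
            density_table=None,
        )


def spectral_overlap(donor: DyeSpecies, acceptor: DyeSpecies) -> float:
    """Monomeric spectral overlap J = int F_D(l) eps_A(l) l^4 dl.

    F_D is the donor emission normalized to unit area over its full grid;
    the integral runs over the union grid of the overlap region
    (trapezoidal quadrature).  Returns 0 when the spectra are disjoint.
    """
    f_d = donor.emission  # already unit-area
    eps_a = acceptor.absorption
    lo = max(f_d.wavelengths[0], eps_a.wavelengths[0])
    hi = min(f_d.wavelengths[-1], eps_a.wavelengths[-1])
    if hi <= lo:
        return 0.0
    grid = np.union1d(f_d.wavelengths, eps_a.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if len(grid) < 2:
        return 0.0
    integrand = f_d.value_at(grid) * eps_a.value_at(grid) * grid**4
    return float(np.trapezoid(integrand, grid))


def forster_radius(J: float, Q_D: float, kappa2: float = 2.0 / 3.0,
                   n_medium: float = 1.4) -> float:
    """Foerster critical distance R0 [nm] from overlap J [M^-1 cm^-1 nm^4]."""
    if min(J, Q_D, kappa2) < 0 or n_medium <= 0:
        raise ValueError("J, Q_D, kappa2 must be >= 0 and n_medium > 0")
    return FORSTER_CONSTANT_NM * (kappa2 * n_medium**-4 * Q_D * J) ** (1.0 / 6.0)


def kappa_squared(mu_i, mu_j, r_vec) -> float:
    """Dipole orientation factor kappa^2 in [0, 4]."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r == 0:
        raise ValueError("kappa^2 is singular at zero separation")
    r_hat = r_vec / r
    mu_i = np.asarray(mu_i, dtype=float) / np.linalg.norm(mu_i)
    mu_j = np.asarray(mu_j, dtype=float) / np.linalg.norm(mu_j)
    kappa = mu_i @ mu_j - 3.0 * (mu_i @ r_hat) * (mu_j @ r_hat)
    return float(kappa**2)


def pairwise_rate(donor: DyeSpecies, R0_iso: float, r: float,
                  kappa2: float | None = None) -> float:
    """Donor->acceptor FRET rate [ns^-1] at separation r [nm].

    ``R0_iso`` is the isotropic (kappa^2 = 2/3) Foerster radius; passing an
    explicit ``kappa2`` rescales by 3 kappa^2 / 2 (None = dynamic averaging).
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    orientational = 1.0 if kappa2 is None else 1.5 * kappa2
    return orientational / donor.lifetime_ns * (R0_iso / r) ** 6


@dataclass
class RateMatrix:
    """Master-equation generator K [ns^-1] plus the site metadata."""

    K: np.ndarray
    species: list[DyeSpecies]
    acceptor_ids: tuple[int, ...] = ()
    n_medium: float = 1.4

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([s.lifetime_ns for s in self.species])

    def to_dataframe(self) -> pd.DataFrame:
        names = [f"{i}:{s.name}" for i, s in enumerate(self.species)]
        return pd.DataFrame(self.K, index=names, columns=names)


def build_rate_matrix(
    dipoles: list[DipoleInstance],
    species,
    n_medium: float = 1.4,
    mode: str = "dynamic",
    r0_overrides: dict | None = None,
    acceptor_ids=(),
) -> RateMatrix:
    """Assemble the n x n FRET rate matrix for a set of placed dipoles.

    ``species`` is either a dict mapping dipole species names to
    DyeSpecies or a per-dipole list.  ``mode`` selects the orientation
    treatment: 'dynamic' (and the positional-sampling modes that keep
    dynamic rotational averaging) uses kappa^2 = 2/3; 'static' evaluates
    the geometric kappa^2 from the dipole orientations.  ``r0_overrides``
    maps ordered (donor_name, acceptor_name) pairs to literature
    isotropic R0 values [nm], bypassing the spectral-overlap route.
    """
    n = len(dipoles)
    if n < 1:
        raise ValueError("need at least one dipole")
    if mode not in ("dynamic", "static"):
        raise ValueError("mode must be 'dynamic' or 'static'")
    if isinstance(species, dict):
        site_species = [species[d.species] for d in dipoles]
    else:
        site_species = list(species)
        if len(site_species) != n:
            raise ValueError("per-site species list must match dipole count")
    r0_overrides = r0_overrides or {}
    j_cache: dict[tuple[str, str], float] = {}
    K = np.zeros((n, n))
    min_r = np.inf
    close_pair = None
    for i in range(n):  # donor
        sp_i = site_species[i]
        for j in range(n):  # acceptor
            if i == j:
                continue
            sp_j = site_species[j]
            r_vec = dipoles[j].position - dipoles[i].position
            r = float(np.linalg.norm(r_vec))
            if r < 1e-9:
                raise ValueError(
                    f"dipoles {i} and {j} are coincident; rates are singular"
                )
            if r < min_r:
                min_r, close_pair = r, (i, j)
            key = (sp_i.name, sp_j.name)
            if key in r0_overrides:
                R0 = float(r0_overrides[key])
            else:
                if key not in j_cache:
                    j_cache[key] = spectral_overlap(sp_i, sp_j)
                R0 = forster_radius(
                    j_cache[key], sp_i.quantum_yield, 2.0 / 3.0, n_medium
                )
            if R0 == 0.0:
                continue
            kappa2 = (
                kappa_squared(dipoles[i].orientation, dipoles[j].orientation, r_vec)
                if mode == "static"
                else None
            )
            K[j, i] += pairwise_rate(sp_i, R0, r, kappa2)
    if min_r < FORSTER_VALIDITY_FLOOR_NM:
        # warn once per process, then demote to debug (density sweeps build
        # thousands of matrices with intentionally close intercalator pairs)
        level = logging.DEBUG if _floor_warned[0] else logging.WARNING
        _floor_warned[0] = True
        log.log(
            level,
            "closest dye pair %s at %.2f nm is below the ~1-2 nm weak-coupling "
            "floor of Foerster theory; rates may be unreliable",
            close_pair,
            min_r,
        )
    # close each column to -1/tau_i: transfer conserves excitons
    for i in range(n):
        K[i, i] = -1.0 / site_species[i].lifetime_ns - (np.sum(K[:, i]) - K[i, i])
    return RateMatrix(K, site_species, tuple(acceptor_ids), n_medium)
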