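"""Ready-made model systems emulating published DNA-photonics benchmarks.

Three families are provided: a single donor--acceptor FRET pair on a
duplex (AF488/Cy5), a photonic wire with intercalated YO-type dyes
bridging PB and Cy3 termini, and seven-helix-bundle light-harvesting
antennas with pyrene donors, Cy3 bridges and an AF647 acceptor in 1:1:1
and 6:6:1 stoichiometries.

All spectra are *synthetic Gaussian bands* with literature-style peak
positions, widths, extinctions, quantum yields and lifetimes — adequate
for exercising the full pipeline and for relative comparisons, not for
absolute reproduction of measured photophysics.  Where literature
isotropic Foerster radii are established (AF488-Cy5 5.2 nm; Py-Cy3
3.7 nm, Cy3-AF647 5.5 nm, Py-AF647 3.3 nm) they are supplied as explicit
R0 overrides so inter-dye couplings do not inherit the synthetic-spectrum
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .averaging import DyeSite, DyeSystem
from .geometry import GeometryParams, RigidPlacement, assemble_bundle, \
    hexagonal_bundle_placements, build_ideal_duplex, NanostructureModel
from .photophysics import DyeSpecies, gaussian_spectrum
from .wire import WireSpec

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "default_species",
    "fret_pair_fixture",
    "photonic_wire_fixture",
    "antenna_fixture",
    "generate_fixture",
]

FIXTURE_KINDS = ("fret_pair", "photonic_wire", "antenna_111", "antenna_661")


#: synthetic bands are truncated at 3 sigma: tabulated dye spectra have
#: finite support, and untruncated Gaussian red tails would produce
#: spurious long-range overlap (e.g. acceptor-to-bridge back transfer)
_SPAN = 3.0


def _species(name, abs_peak, abs_sigma, eps_max, em_peak, em_sigma, Q, tau,
             density_table=None) -> DyeSpecies:
    return DyeSpecies(
        name,
        gaussian_spectrum(abs_peak, abs_sigma, eps_max, span=_SPAN),
        gaussian_spectrum(em_peak, em_sigma, 1.0, span=_SPAN),
        quantum_yield=Q,
        lifetime_ns=tau,
        density_table=density_table,
    )


def default_species() -> dict[str, DyeSpecies]:
    """Synthetic-Gaussian photophysics for the fixture dyes (see module doc)."""
    return {
        "AF488": _species("AF488", 495, 25, 73000, 520, 25, 0.92, 4.1),
        "Cy5": _species("Cy5", 650, 28, 250000, 670, 30, 0.27, 1.0),
        "PB": _species("PB", 405, 22, 37000, 455, 25, 0.78, 3.5),
        "Cy3": _species("Cy3", 550, 25, 150000, 570, 25, 0.15, 1.0),
        # intercalator: minimal Stokes shift sustains homo-FRET; (Q, tau)
        # decline mildly with binding density (self-quenching at high loading)
        "YO": _species(
            "YO", 491, 18, 52000, 509, 22, 0.44, 2.2,
            density_table=((0.0, 0.25, 0.5), (0.50, 0.44, 0.38), (2.4, 2.2, 2.0)),
        ),
        "Py": _species("Py", 380, 18, 40000, 400, 18, 0.65, 1.5),
        "AF647": _species("AF647", 650, 28, 270000, 670, 28, 0.33, 1.0),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Selector for a fixture system."""

    kind: str
    size: int = 0  # bp separation (fret_pair) or wire length in bp
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}"
            )


@dataclass
class FixtureBundle:
    """A self-contained fixture: structure + dye system + run metadata."""

    kind: str
    structure: NanostructureModel | None
    system: DyeSystem | None
    wire: WireSpec | None = None
    excitation_wavelength: float = 0.0
    acceptor_readout_wavelength: float = 0.0
    metadata: dict = field(default_factory=dict)


#: AV parameters of a C6-linked cyanine/AF dye (FPS-style defaults)
FRET_PAIR_AV_PARAMS = {
    "linker_length_nm": 2.0,
    "linker_width_nm": 0.45,
    "dye_radius_nm": 0.35,
    "grid_spacing_nm": 0.2,
}


def fret_pair_fixture(separation_bp: int = 10, tethered: bool = False) -> FixtureBundle:
    """AF488 donor and Cy5 acceptor separated by an integer number of base
    pairs on an ideal duplex, with the literature R0 of 5.2 nm.

    By default the dipoles sit at the base-pair frame origins (fixed-bp
    placement, exact integer-rise separation); with ``tethered=True`` the
    dyes get real accessible volumes computed on the atomic model from
    C6-linker AV parameters, for positional-averaging studies.
    """
    if separation_bp < 1:
        raise ValueError("separation must be at least 1 bp")
    geom = GeometryParams()
    n_bp = separation_bp + 11
    duplex = build_ideal_duplex(("ATGC" * n_bp)[:n_bp], geom)
    model = NanostructureModel({"duplex": duplex}, {"duplex": RigidPlacement()})
    frames = model.global_frames("duplex")
    b0 = 5
    if tethered:
        from .accessible_volume import AVParams, compute_accessible_volume
        from .atoms import generate_atomic_model

        atomic = generate_atomic_model(model)
        params = AVParams(
            FRET_PAIR_AV_PARAMS["linker_length_nm"],
            FRET_PAIR_AV_PARAMS["linker_width_nm"],
            FRET_PAIR_AV_PARAMS["dye_radius_nm"],
            FRET_PAIR_AV_PARAMS["grid_spacing_nm"],
        )
        sites = [
            DyeSite(
                name,
                av=compute_accessible_volume(atomic, ("A", bp + 1, "C5'"), params),
            )
            for name, bp in (("AF488", b0), ("Cy5", b0 + separation_bp))
        ]
    else:
        sites = [
            DyeSite("AF488", position=frames[b0].origin),
            DyeSite("Cy5", position=frames[b0 + separation_bp].origin),
        ]
    system = DyeSystem(
        sites,
        default_species(),
        acceptor_ids=(1,),
        r0_overrides={("AF488", "Cy5"): 5.2},
    )
    return FixtureBundle(
        "fret_pair",
        model,
        system,
        excitation_wavelength=495.0,
        acceptor_readout_wavelength=650.0,
        metadata={
            "separation_bp": separation_bp,
            "R0_nm": 5.2,
            "av_params": dict(FRET_PAIR_AV_PARAMS),
            "tethered": tethered,
        },
    )


def photonic_wire_fixture(n_bp: int = 20) -> FixtureBundle:
    """PB -> YO-bridge -> Cy3 photonic wire of ``n_bp`` base pairs."""
    wire = WireSpec(
        n_bp=n_bp,
        species_table=default_species(),
        donor="PB",
        acceptor="Cy3",
        intercalator="YO",
    )
    return FixtureBundle(
        "photonic_wire",
        None,
        None,
        wire=wire,
        excitation_wavelength=405.0,
        acceptor_readout_wavelength=550.0,
        metadata={"n_bp": n_bp, "max_density_per_bp": 0.5},
    )


_ANTENNA_R0 = {
    ("Py", "Cy3"): 3.7,
    ("Cy3", "AF647"): 5.5,
    ("Py", "AF647"): 3.3,
}


def _antenna_positions(kind: str) -> list[tuple[str, np.ndarray]]:
    if kind == "antenna_111":
        # triangle with the printed mean-position distances:
        # Py-Cy3 1.7 nm, Cy3-AF 3.1 nm, Py-AF 3.1 nm
        return [
            ("Py", np.array([0.0, 0.0, 0.0])),
            ("Cy3", np.array([1.7, 0.0, 0.0])),
            ("AF647", np.array([0.85, np.sqrt(3.1**2 - 0.85**2), 0.0])),
        ]
    # 6:6:1 — AF647 on the center helix axis; six Cy3 at 1.6 nm radial
    # distance with axial staggering spreading the Cy3-AF separations over
    # 1.8-4.3 nm; each Py further along its helix with Py-Cy3 spacings
    # spread over 1.5-2.4 nm
    cy3_af = [1.8, 2.3, 2.8, 3.3, 3.8, 4.3]
    py_cy3 = [1.5, 1.68, 1.86, 2.04, 2.22, 2.4]
    radial = 1.6
    out = [("AF647", np.array([0.0, 0.0, 0.0]))]
    for k in range(6):
        ang = np.pi / 3.0 * k
        z = np.sqrt(cy3_af[k] ** 2 - radial**2) * (1 if k % 2 == 0 else -1)
        cy3 = np.array([radial * np.cos(ang), radial * np.sin(ang), z])
        py = cy3 + np.array([0.0, 0.0, np.sign(z) * py_cy3[k]])
        out.append((f"Cy3", cy3))
        out.append((f"Py", py))
    return out


def antenna_fixture(kind: str = "antenna_661") -> FixtureBundle:
    """Seven-helix bundle antenna (1:1:1 or 6:6:1 Py:Cy3:AF647).

    Dye sites are fixed mean positions consistent with the published
    inter-dye distance ranges; couplings use literature R0 overrides
    (Py-Cy3 3.7, Cy3-AF 5.5, Py-AF 3.3 nm); excitation at 380 nm and
    direct-acceptor readout at 620 nm.
    """
    if kind not in ("antenna_111", "antenna_661"):
        raise ValueError("kind must be antenna_111 or antenna_661")
    geom = GeometryParams()
    placements = hexagonal_bundle_placements(geom.interhelix_spacing)
    seq = ("ATGC" * 8)[:30]
    structure = assemble_bundle(
        [(f"H{k}", seq, pl) for k, pl in enumerate(placements)], geom
    )
    species = default_species()
    entries = _antenna_positions(kind)
    sites = [DyeSite(name, position=pos) for name, pos in entries]
    acceptor_ids = tuple(i for i, (name, _) in enumerate(entries) if name == "AF647")
    system = DyeSystem(
        sites, species, acceptor_ids=acceptor_ids, r0_overrides=dict(_ANTENNA_R0)
    )
    return FixtureBundle(
        kind,
        structure,
        system,
        excitation_wavelength=380.0,
        acceptor_readout_wavelength=620.0,
        metadata={
            "stoichiometry": "1:1:1" if kind == "antenna_111" else "6:6:1",
            "n_donors": sum(1 for name, _ in entries if name == "Py"),
        },
    )


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Build the fixture selected by ``spec`` (see FIXTURE_KINDS)."""
    if spec.kind == "fret_pair":
        return fret_pair_fixture(spec.size or 10)
    if spec.kind == "photonic_wire":
        return photonic_wire_fixture(spec.size or 20)
    return antenna_fixture(spec.kind)
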