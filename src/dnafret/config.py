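"""YAML system configuration: schema, validation, and object construction.

A config file describes one run end to end: the structure (sequences and
placements), the dye sites (fixed positions, frame anchors, or tethered
attachments with AV parameters), the photophysics tables (two-column CSV
spectra), the averaging mode, acceptors, excitation/readout wavelengths
and an optional irradiance table.  All physical quantities carry explicit
unit suffixes in their key names.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .accessible_volume import AVParams
from .averaging import AveragingMode, DyeSite, DyeSystem
from .geometry import GeometryParams, RigidPlacement, assemble_bundle
from .photophysics import DyeSpecies, Spectrum, read_spectrum_csv

__all__ = ["ConfigError", "SystemConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or incomplete system configuration."""


@dataclass
class SystemConfig:
    """Validated configuration plus constructed model objects."""

    raw: dict
    path: Path | None
    seed: int
    n_medium: float
    averaging: AveragingMode
    species_table: dict[str, DyeSpecies]
    structure: object | None  # NanostructureModel
    dye_specs: list[dict]
    acceptor_ids: tuple[int, ...]
    r0_overrides: dict
    excitation_wavelength: float | None
    acceptor_readout_wavelength: float | None
    irradiance: Spectrum | None
    wire: dict | None = None
    av_params: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return mapping[key]


def _load_species(entry: dict, base: Path) -> DyeSpecies:
    name = _require(entry, "name", "species")
    for key in ("absorption_csv", "emission_csv"):
        p = base / _require(entry, key, f"species {name}")
        if not p.exists():
            raise ConfigError(f"species {name}: spectra file not found: {p}")
    absorption = read_spectrum_csv(base / entry["absorption_csv"])
    emission = read_spectrum_csv(base / entry["emission_csv"])
    table = None
    if "density_table" in entry:
        dt = entry["density_table"]
        table = (
            tuple(dt["density_per_bp"]),
            tuple(dt["quantum_yield"]),
            tuple(dt["lifetime_ns"]),
        )
    return DyeSpecies(
        name,
        absorption,
        emission,
        quantum_yield=float(_require(entry, "quantum_yield", f"species {name}")),
        lifetime_ns=float(_require(entry, "lifetime_ns", f"species {name}")),
        density_table=table,
    )


def _load_structure(section: dict | None):
    if not section:
        return None
    geom_raw = section.get("geometry", {})
    geom = GeometryParams(
        axial_rise=float(geom_raw.get("axial_rise_nm", 0.34)),
        twist_per_bp=float(geom_raw.get("twist_per_bp_deg", 360.0 / 10.5)),
        helix_radius=float(geom_raw.get("helix_radius_nm", 1.0)),
        interhelix_spacing=float(geom_raw.get("interhelix_spacing_nm", 2.5)),
    )
    specs = []
    for helix in _require(section, "helices", "structure"):
        ident = _require(helix, "id", "structure helix")
        seq = _require(helix, "sequence", f"helix {ident}")
        origin = np.array(helix.get("origin_nm", [0.0, 0.0, 0.0]), dtype=float)
        triad = np.array(helix.get("triad", np.eye(3).tolist()), dtype=float).reshape(3, 3)
        specs.append((ident, seq, RigidPlacement(origin, triad)))
    try:
        return assemble_bundle(specs, geom)
    except ValueError as exc:
        raise ConfigError(f"structure: {exc}") from exc


def load_config(source) -> SystemConfig:
    """Load and validate a YAML config file (or an equivalent dict)."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        base = path.parent
    else:
        raw = dict(source)
        path = None
        base = Path(".")
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    species_table = {}
    for entry in raw.get("species", []):
        sp = _load_species(entry, base)
        species_table[sp.name] = sp

    structure = _load_structure(raw.get("structure"))

    dye_specs = raw.get("dyes", [])
    for i, d in enumerate(dye_specs):
        name = _require(d, "species", f"dye site {i}")
        if name not in species_table:
            raise ConfigError(f"dye site {i}: unknown species {name!r}")
        if not any(k in d for k in ("position_nm", "anchor", "attachment_atom")):
            raise ConfigError(
                f"dye site {i}: needs position_nm, anchor, or attachment_atom"
            )

    acceptors = tuple(int(a) for a in raw.get("acceptors", ()))
    for a in acceptors:
        if not 0 <= a < len(dye_specs):
            raise ConfigError(f"acceptor id {a} does not match any dye site")

    overrides = {}
    for o in raw.get("r0_overrides", []):
        overrides[(o["donor"], o["acceptor"])] = float(o["r0_nm"])

    av_raw = raw.get("averaging", {})
    averaging = AveragingMode(
        mode=av_raw.get("mode", "mean_position"),
        n_samples=int(av_raw.get("n_samples", 500)),
        seed=int(raw.get("seed", 0)),
    )

    irradiance = None
    if raw.get("irradiance_csv"):
        p = base / raw["irradiance_csv"]
        if not p.exists():
            raise ConfigError(f"irradiance file not found: {p}")
        irradiance = read_spectrum_csv(p)

    return SystemConfig(
        raw=raw,
        path=path,
        seed=int(raw.get("seed", 0)),
        n_medium=float(raw.get("n_medium", 1.4)),
        averaging=averaging,
        species_table=species_table,
        structure=structure,
        dye_specs=dye_specs,
        acceptor_ids=acceptors,
        r0_overrides=overrides,
        excitation_wavelength=raw.get("excitation_wavelength_nm"),
        acceptor_readout_wavelength=raw.get("acceptor_readout_wavelength_nm"),
        irradiance=irradiance,
        wire=raw.get("wire"),
        av_params=raw.get("av_defaults", {}),
    )


def build_dye_system(config: SystemConfig):
    """Construct the DyeSystem from a validated config: resolve fixed
    positions, frame anchors and tethered (AV) attachments."""
    from .atoms import generate_atomic_model
    from .accessible_volume import compute_accessible_volume
    from .dyes import FixedDyeFrame, place_fixed_dye

    sites = []
    atomic = None
    for i, d in enumerate(config.dye_specs):
        if "position_nm" in d:
            orientation = d.get("orientation")
            sites.append(
                DyeSite(
                    d["species"],
                    position=np.array(d["position_nm"], dtype=float),
                    orientation=None if orientation is None else np.array(orientation),
                )
            )
        elif "anchor" in d:
            if config.structure is None:
                raise ConfigError(f"dye site {i}: anchor given but no structure")
            anchor = d["anchor"]
            spec = FixedDyeFrame(
                duplex_id=anchor["duplex"],
                anchor_kind=anchor.get("kind", "bp"),
                anchor_index=int(anchor["index"]),
                offset=tuple(d.get("offset_nm", (0.0, 0.0, 0.0))),
                orientation=tuple(d.get("orientation", (1.0, 0.0, 0.0))),
                species=d["species"],
            )
            dip = place_fixed_dye(config.structure, spec)
            sites.append(
                DyeSite(d["species"], position=dip.position, orientation=dip.orientation)
            )
        else:
            if config.structure is None:
                raise ConfigError(f"dye site {i}: tethered site needs a structure")
            if atomic is None:
                atomic = generate_atomic_model(config.structure)
            av_raw = {**config.av_params, **d.get("av", {})}
            params = AVParams(
                linker_length=float(av_raw.get("linker_length_nm", 2.0)),
                linker_width=float(av_raw.get("linker_width_nm", 0.45)),
                dye_radius=float(av_raw.get("dye_radius_nm", 0.35)),
                grid_spacing=float(av_raw.get("grid_spacing_nm", 0.1)),
            )
            av = compute_accessible_volume(
                atomic, tuple(d["attachment_atom"]), params
            )
            sites.append(DyeSite(d["species"], av=av))
    return DyeSystem(
        sites,
        config.species_table,
        acceptor_ids=config.acceptor_ids,
        n_medium=config.n_medium,
        r0_overrides=config.r0_overrides,
    )
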