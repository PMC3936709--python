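"""Atomic-level models: reference base pairs placed at base-pair frames.

Each base-pair frame receives a copy of a reference base pair (atoms in
the local frame: origin at the base-pair center, z along the helix axis)
rigid-transformed by the frame's origin and triad.  The packaged
references are *synthetic* idealized B-form coordinates built from
cylindrical geometry (backbone phosphorus at ~0.94 nm radius, C1' at
~0.59 nm with a 1.04 nm C1'-C1' separation); they reproduce the steric
envelope and canonical distances of B-DNA but are not crystallographic.
Users may substitute crystallographic fragments via ``load_reference_pdb``.

Coordinates are nm internally and Angstrom in PDB files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np

from .geometry import NanostructureModel

__all__ = [
    "ReferenceBasePair",
    "AtomicModel",
    "default_reference_base_pairs",
    "generate_atomic_model",
    "write_pdb",
    "read_pdb",
    "load_reference_pdb",
]

log = logging.getLogger(__name__)

# (atom name, element, radius nm, azimuth deg, z nm) for one nucleotide of
# the reference strand; the complementary strand is mirrored (azimuth and z
# negated).  Azimuths are measured from the pseudo-dyad (+x) axis.
_NUCLEOTIDE_TEMPLATE = [
    ("P", "P", 0.94, 95.0, 0.09),
    ("O5'", "O", 0.90, 88.0, 0.06),
    ("C5'", "C", 0.86, 81.0, 0.04),
    ("C4'", "C", 0.81, 74.0, 0.02),
    ("C3'", "C", 0.78, 68.0, 0.05),
    ("O3'", "O", 0.76, 62.0, 0.08),
    ("C1'", "C", 0.59, 61.8, 0.00),
    ("N9", "N", 0.48, 50.0, 0.00),  # renamed N1 for pyrimidines
    ("C4", "C", 0.30, 30.0, 0.00),
    ("C6", "C", 0.15, 10.0, 0.00),
]


@dataclass(frozen=True)
class ReferenceBasePair:
    """Reference atoms of one base pair in the local base-pair frame.

    ``atoms`` is a list of (atom_name, element, residue_name, strand, xyz)
    with strand 1 the reference strand and strand 2 its complement; xyz nm.
    """

    base_identity: str
    atoms: tuple

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("reference base pair has no atoms")
        for *_, xyz in self.atoms:
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite reference coordinate")


def _nucleotide_atoms(base: str, strand: int):
    purine = base in "AG"
    resname = "D" + base
    sign = 1.0 if strand == 1 else -1.0
    atoms = []
    for name, element, r, az_deg, z in _NUCLEOTIDE_TEMPLATE:
        if name == "N9" and not purine:
            name = "N1"
        az = np.deg2rad(sign * az_deg)
        xyz = np.array([r * np.cos(az), r * np.sin(az), sign * z])
        atoms.append((name, element, resname, strand, xyz))
    return atoms


_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def default_reference_base_pairs() -> dict[str, ReferenceBasePair]:
    """Synthetic idealized references for the four base pairs."""
    refs = {}
    for base in "ATGC":
        identity = base + _COMPLEMENT[base]
        atoms = tuple(
            _nucleotide_atoms(base, 1) + _nucleotide_atoms(_COMPLEMENT[base], 2)
        )
        refs[identity] = ReferenceBasePair(identity, atoms)
    return refs


@dataclass
class AtomicModel:
    """Flat atomic model: parallel arrays of metadata plus global coords (nm)."""

    chain_ids: list[str]
    res_seq: np.ndarray
    res_names: list[str]
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) nm

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, chain_id: str, res_seq: int, atom_name: str) -> int:
        """Index of a single atom; raises KeyError if absent."""
        for i in range(self.n_atoms):
            if (
                self.chain_ids[i] == chain_id
                and self.res_seq[i] == res_seq
                and self.atom_names[i] == atom_name
            ):
                return i
        raise KeyError(f"no atom {atom_name} in chain {chain_id} residue {res_seq}")


_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def generate_atomic_model(
    model: NanostructureModel,
    refs: dict[str, ReferenceBasePair] | None = None,
) -> AtomicModel:
    """Place reference base-pair atoms at every global base-pair frame.

    Two chains per duplex (reference strand 5'->3', complement reversed),
    chain letters assigned in duplex order.
    """
    refs = refs or default_reference_base_pairs()
    chain_ids, res_names, atom_names, elements = [], [], [], []
    res_seq, coords = [], []
    for d_index, ident in enumerate(model.duplex_ids):
        frames = model.global_frames(ident)
        n = len(frames)
        chain1 = _CHAIN_LETTERS[(2 * d_index) % len(_CHAIN_LETTERS)]
        chain2 = _CHAIN_LETTERS[(2 * d_index + 1) % len(_CHAIN_LETTERS)]
        for frame in frames:
            identity = frame.base_identity
            if identity not in refs:
                raise KeyError(f"no reference base pair for identity {identity!r}")
            for name, element, resname, strand, xyz in refs[identity].atoms:
                global_xyz = frame.origin + frame.triad @ xyz
                chain_ids.append(chain1 if strand == 1 else chain2)
                # 5'->3' numbering on each strand: complement runs antiparallel
                res_seq.append(frame.index + 1 if strand == 1 else n - frame.index)
                res_names.append(resname)
                atom_names.append(name)
                elements.append(element)
                coords.append(global_xyz)
    return AtomicModel(
        chain_ids,
        np.array(res_seq, dtype=int),
        res_names,
        atom_names,
        elements,
        np.array(coords),
    )


def _to_gemmi(model: AtomicModel) -> gemmi.Structure:
    # gemmi's add_residue/add_chain copy their argument, so the hierarchy
    # is assembled bottom-up: atoms into residues, residues into chains
    structure = gemmi.Structure()
    structure.name = "dnafret"
    gm = gemmi.Model("1")
    order = np.lexsort((model.res_seq, np.array([ord(c[0]) for c in model.chain_ids])))
    grouped: dict[str, dict[int, list[int]]] = {}
    for i in order:
        grouped.setdefault(model.chain_ids[i], {}).setdefault(
            int(model.res_seq[i]), []
        ).append(i)
    serial = 1
    for cid, residues in grouped.items():
        chain = gemmi.Chain(cid)
        for seq, atom_idx in residues.items():
            res = gemmi.Residue()
            res.name = model.res_names[atom_idx[0]]
            res.seqid = gemmi.SeqId(seq, " ")
            for i in atom_idx:
                atom = gemmi.Atom()
                atom.name = model.atom_names[i]
                atom.element = gemmi.Element(model.elements[i])
                x, y, z = 10.0 * model.coords[i]  # nm -> Angstrom
                atom.pos = gemmi.Position(x, y, z)
                atom.serial = serial
                serial += 1
                res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    structure.add_model(gm)
    return structure


def write_pdb(model: AtomicModel, path) -> None:
    """Write standard PDB ATOM records (coordinates in Angstrom)."""
    if model.n_atoms == 0:
        raise ValueError("cannot write an empty atomic model")
    if model.n_atoms > 99999:
        log.warning(
            "model has %d atoms (> 99999); serial numbers use the hybrid-36 "
            "extension, some viewers may object",
            model.n_atoms,
        )
    structure = _to_gemmi(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_pdb(path) -> AtomicModel:
    """Read a PDB file back into an AtomicModel (coordinates in nm)."""
    structure = gemmi.read_structure(str(path))
    chain_ids, res_names, atom_names, elements = [], [], [], []
    res_seq, coords = [], []
    for gm in structure:
        for chain in gm:
            for res in chain:
                for atom in res:
                    chain_ids.append(chain.name)
                    res_seq.append(res.seqid.num)
                    res_names.append(res.name)
                    atom_names.append(atom.name)
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x / 10.0, atom.pos.y / 10.0, atom.pos.z / 10.0])
        break  # first model only
    return AtomicModel(
        chain_ids,
        np.array(res_seq, dtype=int),
        res_names,
        atom_names,
        elements,
        np.array(coords),
    )


def load_reference_pdb(path, base_identity: str) -> ReferenceBasePair:
    """Load a user reference base-pair fragment from PDB (local-frame coords,
    Angstrom on disk -> nm in memory); first chain = reference strand."""
    model = read_pdb(path)
    first_chain = model.chain_ids[0]
    atoms = tuple(
        (
            model.atom_names[i],
            model.elements[i],
            model.res_names[i],
            1 if model.chain_ids[i] == first_chain else 2,
            model.coords[i],
        )
        for i in range(model.n_atoms)
    )
    return ReferenceBasePair(base_identity, atoms)
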