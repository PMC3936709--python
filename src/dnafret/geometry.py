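"""Base-pair-frame models of DNA duplexes and multi-helix bundles.

A duplex is represented as an ordered chain of rigid base-pair frames:
each base pair carries an origin (nm) and a right-handed orthonormal
triad whose columns are the local x/y/z axes, with z along the local
helix axis and the origin at the base-pair center.  Successive frames
are related by a step transform (axial rise along z, twist about z,
plus optional bend/stretch deviations), so helical geometry, local
perturbations such as intercalation, and thermal deformations all
compose through the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryParams",
    "BasePairFrame",
    "DuplexModel",
    "NanostructureModel",
    "RigidPlacement",
    "build_ideal_duplex",
    "apply_intercalation_geometry",
    "assemble_bundle",
    "hexagonal_bundle_placements",
    "frames_from_steps",
    "rotation_z",
]

_VALID_BASES = set("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: default B-form helical geometry: 0.34 nm/bp rise, 10.5 bp/turn
DEFAULT_RISE_NM = 0.34
DEFAULT_TWIST_DEG = 360.0 / 10.5

ORTHONORMAL_TOL = 1e-9


@dataclass(frozen=True)
class GeometryParams:
    """Helical geometry of an ideal B-form duplex.

    Parameters
    ----------
    axial_rise : float
        Axial rise per base-pair step, nm (B-form: 0.34).
    twist_per_bp : float
        Helical twist per step, degrees (B-form: ~34.3, 10.5 bp/turn).
    helix_radius : float
        Radius used when placing backbone atoms, nm.
    interhelix_spacing : float
        Center-to-center spacing of packed helices in bundles, nm.
    """

    axial_rise: float = DEFAULT_RISE_NM
    twist_per_bp: float = DEFAULT_TWIST_DEG
    helix_radius: float = 1.0
    interhelix_spacing: float = 2.5

    def __post_init__(self):
        if self.axial_rise <= 0:
            raise ValueError("axial_rise must be positive")
        if not 0 < self.twist_per_bp < 360:
            raise ValueError("twist_per_bp must lie in (0, 360) degrees")


@dataclass(frozen=True)
class BasePairFrame:
    """Rigid-body pose of one base pair: origin (nm) + orthonormal triad."""

    index: int
    origin: np.ndarray
    triad: np.ndarray
    base_identity: str  # AT, TA, GC or CG (first letter = reference strand)

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        triad = np.asarray(self.triad, dtype=float)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "triad", triad)
        if origin.shape != (3,) or triad.shape != (3, 3):
            raise ValueError("origin must be a 3-vector and triad a 3x3 matrix")
        if not frame_is_orthonormal(triad):
            raise ValueError(f"triad of frame {self.index} is not a proper rotation")
        if self.base_identity not in ("AT", "TA", "GC", "CG"):
            raise ValueError(f"unknown base identity {self.base_identity!r}")


def frame_is_orthonormal(triad: np.ndarray, tol: float = 1e-8) -> bool:
    return (
        np.linalg.norm(triad.T @ triad - np.eye(3)) < tol
        and np.linalg.det(triad) > 0
    )


def rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_xy(bx: float, by: float) -> np.ndarray:
    """Rotation by small bend angles about local x then y."""
    cx, sx = np.cos(bx), np.sin(bx)
    cy, sy = np.cos(by), np.sin(by)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]], dtype=float)
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]], dtype=float)
    return rx @ ry


def frames_from_steps(
    sequence: str,
    rises: np.ndarray,
    twists_rad: np.ndarray,
    bends_rad: np.ndarray | None = None,
) -> list[BasePairFrame]:
    """Chain base-pair frames from per-step rises/twists (and optional bends).

    Frame 0 sits at the origin with the identity triad.  Step i translates
    by ``rises[i]`` along the current local z and rotates the triad by
    ``twists_rad[i]`` about it; ``bends_rad`` (n-1, 2) adds small rotations
    about the local x and y axes (thermal bending).
    """
    n = len(sequence)
    origin = np.zeros(3)
    triad = np.eye(3)
    frames = [BasePairFrame(0, origin, triad, _identity_of(sequence[0]))]
    for i in range(n - 1):
        origin = origin + rises[i] * triad[:, 2]
        step = rotation_z(twists_rad[i])
        if bends_rad is not None:
            step = step @ _rotation_xy(bends_rad[i, 0], bends_rad[i, 1])
        triad = triad @ step
        # re-orthonormalize to keep the invariant tight over long chains
        u, _, vt = np.linalg.svd(triad)
        triad = u @ vt
        frames.append(BasePairFrame(i + 1, origin, triad, _identity_of(sequence[i + 1])))
    return frames


def _identity_of(base: str) -> str:
    return base + _COMPLEMENT[base]


@dataclass
class DuplexModel:
    """A duplex as a chain of base-pair frames plus its per-step geometry."""

    sequence: str
    frames: list[BasePairFrame]
    step_rises: np.ndarray  # nm, length n-1
    step_twists: np.ndarray  # rad, length n-1
    intercalation_sites: tuple[int, ...] = ()

    def __post_init__(self):
        if len(self.frames) != len(self.sequence):
            raise ValueError("frame count must equal sequence length")
        self.step_rises = np.asarray(self.step_rises, dtype=float)
        self.step_twists = np.asarray(self.step_twists, dtype=float)

    @property
    def n_bp(self) -> int:
        return len(self.sequence)

    @property
    def n_steps(self) -> int:
        return len(self.sequence) - 1

    def origins(self) -> np.ndarray:
        return np.array([f.origin for f in self.frames])

    def contour_length(self) -> float:
        return float(np.sum(self.step_rises))

    def end_to_end_distance(self) -> float:
        return float(np.linalg.norm(self.frames[-1].origin - self.frames[0].origin))

    def step_frame(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """Mid-step frame: mean of flanking origins, triad at half the step twist."""
        if not 0 <= step < self.n_steps:
            raise IndexError(f"step {step} out of range [0, {self.n_steps})")
        f0, f1 = self.frames[step], self.frames[step + 1]
        origin = 0.5 * (f0.origin + f1.origin)
        triad = f0.triad @ rotation_z(0.5 * self.step_twists[step])
        return origin, triad


def build_ideal_duplex(sequence: str, geom: GeometryParams | None = None) -> DuplexModel:
    """Build a straight ideal duplex: frame 0 at the origin, identity triad,
    each step translating by the axial rise along z and twisting about it."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    for pos, base in enumerate(sequence):
        if base not in _VALID_BASES:
            raise ValueError(
                f"invalid base {base!r} at position {pos}: alphabet is A, C, G, T"
            )
    geom = geom or GeometryParams()
    n = len(sequence)
    rises = np.full(n - 1, geom.axial_rise)
    twists = np.full(n - 1, np.deg2rad(geom.twist_per_bp))
    frames = frames_from_steps(sequence, rises, twists)
    return DuplexModel(sequence, frames, rises, twists)


def apply_intercalation_geometry(
    duplex: DuplexModel,
    sites,
    delta_rise: float = 0.34,
    delta_twist: float = -16.0,
) -> DuplexModel:
    """Elongate and unwind the duplex at intercalated steps.

    Each listed inter-bp step gains ``delta_rise`` nm of rise and
    ``delta_twist`` degrees of twist; downstream frames propagate rigidly.
    Defaults emulate a cyanine-family intercalator (one extra base-pair
    rise and local unwinding); exact values are dye-specific config.
    """
    sites = tuple(int(s) for s in sites)
    if len(set(sites)) != len(sites):
        raise ValueError("intercalation sites must be distinct")
    for s in sites:
        if not 0 <= s < duplex.n_steps:
            raise IndexError(f"intercalation site {s} out of range [0, {duplex.n_steps})")
    if not sites:
        return replace(duplex, intercalation_sites=())
    rises = duplex.step_rises.copy()
    twists = duplex.step_twists.copy()
    idx = np.array(sites)
    rises[idx] += delta_rise
    twists[idx] += np.deg2rad(delta_twist)
    frames = frames_from_steps(duplex.sequence, rises, twists)
    return DuplexModel(duplex.sequence, frames, rises, twists, tuple(sorted(sites)))


@dataclass(frozen=True)
class RigidPlacement:
    """Rigid transform placing a duplex in the assembly frame."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    triad: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        triad = np.asarray(self.triad, dtype=float)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "triad", triad)
        if not frame_is_orthonormal(triad):
            raise ValueError("placement triad must be a proper rotation")

    def apply_point(self, p: np.ndarray) -> np.ndarray:
        return self.origin + self.triad @ p

    def apply_frame(self, frame: BasePairFrame) -> BasePairFrame:
        return BasePairFrame(
            frame.index,
            self.apply_point(frame.origin),
            self.triad @ frame.triad,
            frame.base_identity,
        )


@dataclass
class NanostructureModel:
    """A set of rigidly placed duplexes (e.g. a multi-helix bundle)."""

    duplexes: dict[str, DuplexModel]
    placements: dict[str, RigidPlacement]

    def __post_init__(self):
        if set(self.duplexes) != set(self.placements):
            raise ValueError("duplex and placement identifiers must match")

    @property
    def duplex_ids(self) -> list[str]:
        return list(self.duplexes)

    def global_frames(self, duplex_id: str) -> list[BasePairFrame]:
        pl = self.placements[duplex_id]
        return [pl.apply_frame(f) for f in self.duplexes[duplex_id].frames]

    def global_step_frame(self, duplex_id: str, step: int):
        origin, triad = self.duplexes[duplex_id].step_frame(step)
        pl = self.placements[duplex_id]
        return pl.apply_point(origin), pl.triad @ triad

    def all_origins(self) -> np.ndarray:
        return np.vstack(
            [np.array([f.origin for f in self.global_frames(d)]) for d in self.duplexes]
        )


def assemble_bundle(
    helix_specs,
    geom: GeometryParams | None = None,
) -> NanostructureModel:
    """Assemble rigidly placed ideal duplexes into a bundle.

    ``helix_specs`` is a sequence of ``(identifier, sequence, RigidPlacement)``
    triples; each duplex is built ideally and then rigidly placed.
    """
    geom = geom or GeometryParams()
    duplexes: dict[str, DuplexModel] = {}
    placements: dict[str, RigidPlacement] = {}
    for ident, sequence, placement in helix_specs:
        if ident in duplexes:
            raise ValueError(f"duplicate duplex identifier {ident!r}")
        duplexes[ident] = build_ideal_duplex(sequence, geom)
        placements[ident] = placement
    return NanostructureModel(duplexes, placements)


def hexagonal_bundle_placements(spacing: float, antiparallel_ring: bool = False):
    """Placements for a seven-helix bundle: one center helix surrounded by a
    hexagonal ring at center-to-center distance ``spacing`` nm, axes parallel
    (or ring helices flipped when ``antiparallel_ring``)."""
    placements = [RigidPlacement(np.zeros(3), np.eye(3))]
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: reverses the helix axis
    for k in range(6):
        ang = np.pi / 3.0 * k
        origin = spacing * np.array([np.cos(ang), np.sin(ang), 0.0])
        triad = flip if antiparallel_ring else np.eye(3)
        placements.append(RigidPlacement(origin, triad))
    return placements
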