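"""Dye dipole placement: fixed-frame dyes and intercalator loading.

A dye is ultimately a point transition dipole: a position plus a unit
orientation vector.  Tethered dyes get their positions from accessible
volumes; intercalated and base-substituted dyes are rigidly attached to
a base-pair frame or an inter-bp step frame with a local offset and a
local orientation that co-rotate with the DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import NanostructureModel

__all__ = [
    "DipoleInstance",
    "FixedDyeFrame",
    "place_fixed_dye",
    "sample_intercalator_loading",
]


@dataclass
class DipoleInstance:
    """Point transition dipole: position (nm) + unit orientation + species."""

    position: np.ndarray
    orientation: np.ndarray
    species: str

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(self.orientation)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"dipole orientation must be unit norm (got {norm})")


@dataclass(frozen=True)
class FixedDyeFrame:
    """Anchor spec for a dye fixed relative to the DNA.

    anchor_kind: 'bp' (base-pair frame) or 'step' (mid-step frame, the
    natural anchor for intercalators); local offset (nm) and orientation
    (unit vector) are expressed in the anchor frame.
    """

    duplex_id: str
    anchor_kind: str
    anchor_index: int
    offset: tuple = (0.0, 0.0, 0.0)
    orientation: tuple = (1.0, 0.0, 0.0)
    species: str = ""

    def __post_init__(self):
        if self.anchor_kind not in ("bp", "step"):
            raise ValueError("anchor_kind must be 'bp' or 'step'")
        norm = float(np.linalg.norm(self.orientation))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("local orientation must be unit norm")


def place_fixed_dye(model: NanostructureModel, spec: FixedDyeFrame) -> DipoleInstance:
    """Rigid-transform a fixed dye's local offset/orientation by its anchor
    frame (bp frame, or interpolated mid-step frame for intercalators)."""
    duplex = model.duplexes[spec.duplex_id]
    if spec.anchor_kind == "bp":
        if not 0 <= spec.anchor_index < duplex.n_bp:
            raise IndexError(f"bp anchor {spec.anchor_index} out of range")
        frame = model.global_frames(spec.duplex_id)[spec.anchor_index]
        origin, triad = frame.origin, frame.triad
    else:
        origin, triad = model.global_step_frame(spec.duplex_id, spec.anchor_index)
    position = origin + triad @ np.asarray(spec.offset, dtype=float)
    orientation = triad @ np.asarray(spec.orientation, dtype=float)
    return DipoleInstance(position, orientation, spec.species)


def _sample_fixed_size_independent_set(
    n_steps: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random set of k pairwise non-adjacent steps out of n_steps.

    Bijection with k-subsets of n_steps - k + 1 slots: choose, sort, and
    shift the i-th chosen slot by i.
    """
    if k == 0:
        return np.empty(0, dtype=int)
    slots = rng.choice(n_steps - k + 1, size=k, replace=False)
    slots.sort()
    return slots + np.arange(k)


def sample_intercalator_loading(
    n_steps: int,
    density: float,
    n_patterns: int,
    seed: int = 0,
    n_bp: int | None = None,
) -> list[np.ndarray]:
    """Random intercalator occupancy patterns with nearest-neighbor exclusion.

    ``density`` is the mean number of dyes per base pair (n_bp defaults to
    n_steps + 1); exclusion caps it at 0.5 dyes/bp.  Each pattern is a sorted
    array of occupied step indices; the number of dyes per pattern is
    randomized between the floor and ceiling of the target mean so that the
    realized mean density matches the target.  Seeded and deterministic.
    """
    if n_bp is None:
        n_bp = n_steps + 1
    if not 0.0 <= density <= 0.5:
        raise ValueError(
            "density must lie in [0, 0.5] dyes/bp: nearest-neighbor exclusion "
            "makes higher loadings unreachable"
        )
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng = np.random.default_rng(seed)
    mean_count = density * n_bp
    k_max = (n_steps + 1) // 2
    base = int(np.floor(mean_count))
    frac = mean_count - base
    patterns = []
    for _ in range(n_patterns):
        k = base + (1 if rng.random() < frac else 0)
        k = min(k, k_max)
        patterns.append(_sample_fixed_size_independent_set(n_steps, k, rng))
    return patterns
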