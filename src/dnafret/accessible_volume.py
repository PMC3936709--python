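"""Accessible volumes (AV) of dyes tethered to DNA by flexible linkers.

The AV is the set of sterically allowed dye positions: grid points
around the attachment atom that (a) can be reached from the attachment
point by a clash-free linker path no longer than the linker length, and
(b) leave room for the dye sphere itself (no structure atom within
dye_radius + its van-der-Waals radius).  Reachability is a geodesic
criterion evaluated by shortest paths on the clash-free grid graph
(26-neighbor Dijkstra); straight clash-free segments are additionally
accepted at their exact Euclidean length, so an unobstructed AV is an
exact ball of the linker length.  The linker path only needs
linker_width/2 of clearance (the dye sphere needs its full radius), and
when the attachment atom sits inside its own bonded-atom shell the path
is seeded from the nearest path-clear cells, as a real linker stub
threads between the bonded neighbors.

This is the single-radius (AV1) variant; ``accessible_volume_av3``
unions three dye radii for ellipsoidal dyes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .atoms import AtomicModel

__all__ = [
    "AVParams",
    "AccessibleVolume",
    "EmptyAccessibleVolumeError",
    "VDW_RADII_NM",
    "compute_accessible_volume",
    "accessible_volume_from_points",
    "accessible_volume_av3",
    "mean_dye_position",
    "sample_dye_positions",
]

#: element van-der-Waals radii, nm
VDW_RADII_NM = {
    "H": 0.110,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "P": 0.180,
    "S": 0.180,
}
_DEFAULT_VDW = 0.17


class EmptyAccessibleVolumeError(RuntimeError):
    """The attachment point is sterically buried: no allowed dye position."""


@dataclass(frozen=True)
class AVParams:
    """Geometric parameters of the AV search.

    linker_length, linker_width, dye_radius and grid_spacing in nm.
    grid_spacing must resolve the dye (<= dye_radius).
    """

    linker_length: float
    linker_width: float = 0.45
    dye_radius: float = 0.35
    grid_spacing: float = 0.1

    def __post_init__(self):
        vals = (self.linker_length, self.linker_width, self.dye_radius, self.grid_spacing)
        if min(vals) <= 0:
            raise ValueError("all AV parameters must be positive")
        if self.grid_spacing > self.dye_radius:
            raise ValueError("grid_spacing must not exceed dye_radius")


@dataclass
class AccessibleVolume:
    """Point cloud of allowed dye positions (nm) on a cubic grid."""

    attachment_point: np.ndarray
    points: np.ndarray  # (n, 3)
    grid_spacing: float

    @property
    def n_points(self) -> int:
        return len(self.points)


def _grid(attachment_point: np.ndarray, L: float, h: float):
    half = int(np.ceil(L / h))
    axis = np.arange(-half, half + 1) * h
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + attachment_point
    ng = 2 * half + 1
    start = (half * ng + half) * ng + half  # flat index of the attachment cell
    return pts, ng, start


_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _geodesic_distances(
    free: np.ndarray, ng: int, h: float, seeds: np.ndarray, seed_dists: np.ndarray
) -> np.ndarray:
    """Shortest path lengths from the attachment through path-clear cells.

    Multi-source Dijkstra via a virtual source node linked to the seed
    cells at their Euclidean offsets (the linker escapes the bonded-atom
    shell around the attachment in a straight stub)."""
    mask3 = free.reshape(ng, ng, ng)
    flat = np.arange(free.size).reshape(ng, ng, ng)
    rows, cols, weights = [], [], []
    for off in _OFFSETS:
        sl_a = tuple(slice(max(0, o), ng + min(0, o)) for o in off)
        sl_b = tuple(slice(max(0, -o), ng + min(0, -o)) for o in off)
        ok = mask3[sl_a] & mask3[sl_b]
        a = flat[sl_a][ok]
        b = flat[sl_b][ok]
        rows.append(a)
        cols.append(b)
        weights.append(np.full(a.size, h * float(np.linalg.norm(off))))
    source = free.size
    rows.append(np.full(len(seeds), source))
    cols.append(seeds)
    weights.append(seed_dists)
    graph = csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(free.size + 1, free.size + 1),
    )
    return dijkstra(graph, directed=False, indices=source)[:-1]


def _line_of_sight(
    candidates: np.ndarray,
    pts: np.ndarray,
    attachment: np.ndarray,
    free3: np.ndarray,
    origin: np.ndarray,
    h: float,
    ng: int,
    skip_radius: float,
) -> np.ndarray:
    """Straight clash-free segment test, evaluated on the path-clearance
    grid; samples within ``skip_radius`` of the attachment are exempt
    (the bonded-atom shell the linker necessarily threads)."""
    if candidates.size == 0:
        return np.zeros(0, dtype=bool)
    targets = pts[candidates]
    dists = np.linalg.norm(targets - attachment, axis=1)
    n_samp = max(2, int(np.ceil(np.max(dists) / h * 2)))
    t = np.linspace(0.0, 1.0, n_samp + 1)[1:]
    seg = attachment + t[None, :, None] * (targets[:, None, :] - attachment)
    idx = np.rint((seg - origin) / h).astype(int)
    idx = np.clip(idx, 0, ng - 1)
    ok = free3[idx[..., 0], idx[..., 1], idx[..., 2]]
    if skip_radius > 0:
        ok |= (t[None, :] * dists[:, None]) < skip_radius
    return ok.all(axis=1)


def accessible_volume_from_points(
    atom_xyz: np.ndarray,
    atom_radii: np.ndarray,
    attachment_point,
    params: AVParams,
) -> AccessibleVolume:
    """AV around ``attachment_point`` given obstacle spheres (positions nm,
    van-der-Waals radii nm).  See module docstring for the criterion."""
    attachment = np.asarray(attachment_point, dtype=float)
    L, h = params.linker_length, params.grid_spacing
    pts, ng, start = _grid(attachment, L, h)
    # two clearance criteria: the linker path needs linker_width/2 of room,
    # the dye sphere itself needs dye_radius
    free_path = np.ones(len(pts), dtype=bool)
    free_dye = np.ones(len(pts), dtype=bool)
    atom_xyz = np.asarray(atom_xyz, dtype=float).reshape(-1, 3)
    atom_radii = np.asarray(atom_radii, dtype=float).ravel()
    if len(atom_xyz):
        for r in np.unique(atom_radii):
            tree = cKDTree(atom_xyz[atom_radii == r])
            dist, _ = tree.query(pts, workers=-1)
            free_path &= dist > r + 0.5 * params.linker_width
            free_dye &= dist > r + params.dye_radius
    euclid = np.linalg.norm(pts - attachment, axis=1)
    if free_path[start]:
        seeds = np.array([start])
        seed_dists = np.zeros(1)
        skip_radius = 0.0
    else:
        # attachment sits inside the bonded-atom shell; the linker stub
        # escapes radially to the nearest path-clear cells
        skip_radius = params.linker_width + 2 * h
        seeds = np.flatnonzero(free_path & (euclid <= skip_radius))
        if seeds.size == 0:
            raise EmptyAccessibleVolumeError(
                "attachment point is sterically buried: no path-clear cell "
                "within reach of the linker stub"
            )
        seed_dists = euclid[seeds]
    geod = _geodesic_distances(free_path, ng, h, seeds, seed_dists)
    allowed = free_dye & (geod <= L)
    # exact straight-linker shortcut for points the grid path overestimates
    free3 = free_path.reshape(ng, ng, ng)
    cand = np.flatnonzero(free_dye & ~allowed & (euclid <= L))
    if cand.size:
        los = _line_of_sight(
            cand, pts, attachment, free3, pts[0], h, ng, skip_radius
        )
        allowed[cand[los]] = True
    if not allowed.any():
        raise EmptyAccessibleVolumeError("no allowed dye positions within linker reach")
    return AccessibleVolume(attachment, pts[allowed], h)


def compute_accessible_volume(
    model: AtomicModel,
    attachment_atom,
    params: AVParams,
    exclude_attachment_atom: bool = True,
) -> AccessibleVolume:
    """AV of a dye tethered at ``attachment_atom`` of an atomic model.

    ``attachment_atom`` is an atom index or a (chain_id, res_seq, atom_name)
    selector.  The attachment atom itself is excluded from the obstacle set
    (the linker emanates from it) unless requested otherwise.
    """
    if isinstance(attachment_atom, (tuple, list)):
        idx = model.select(*attachment_atom)
    else:
        idx = int(attachment_atom)
    attachment = model.coords[idx]
    keep = np.ones(model.n_atoms, dtype=bool)
    if exclude_attachment_atom:
        keep[idx] = False
    radii = np.array([VDW_RADII_NM.get(e, _DEFAULT_VDW) for e in model.elements])
    return accessible_volume_from_points(
        model.coords[keep], radii[keep], attachment, params
    )


def accessible_volume_av3(
    model: AtomicModel,
    attachment_atom,
    params: AVParams,
    dye_radii: tuple[float, float, float],
) -> AccessibleVolume:
    """Three-radius (AV3) variant for ellipsoidal dyes: union of the
    single-radius AVs computed at each of the three radii."""
    avs = []
    for r in dye_radii:
        p = AVParams(
            params.linker_length, params.linker_width, r, min(params.grid_spacing, r)
        )
        avs.append(compute_accessible_volume(model, attachment_atom, p))
    h = params.grid_spacing
    keys = np.unique(
        np.round(np.vstack([av.points for av in avs]) / h).astype(int), axis=0
    )
    return AccessibleVolume(avs[0].attachment_point, keys * h, h)


def mean_dye_position(av: AccessibleVolume) -> np.ndarray:
    """Unweighted centroid of the allowed points (the AV mean position)."""
    if av.n_points == 0:
        raise ValueError("accessible volume is empty")
    return av.points.mean(axis=0)


def sample_dye_positions(av: AccessibleVolume, n: int, seed: int = 0) -> np.ndarray:
    """Uniform-with-replacement positions from the AV point cloud; seeded."""
    if n <= 0:
        raise ValueError("n must be positive")
    if av.n_points == 0:
        raise ValueError("accessible volume is empty")
    rng = np.random.default_rng(seed)
    return av.points[rng.integers(0, av.n_points, size=n)]
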