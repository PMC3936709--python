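"""Interchange formats: base-pair frame JSON and AV point-cloud export."""

from __future__ import annotations

import json

import numpy as np

from .accessible_volume import AccessibleVolume
from .geometry import BasePairFrame, DuplexModel

__all__ = [
    "frames_to_json",
    "frames_from_json",
    "duplex_from_frames_json",
    "write_av_xyz",
    "write_av_json",
]


def frames_to_json(frames: list[BasePairFrame], path=None) -> str:
    """Serialize frames as JSON records (index, origin[3], triad[9] row-major,
    base_identity); returns the string, optionally writing it to ``path``."""
    records = [
        {
            "index": f.index,
            "origin": f.origin.tolist(),
            "triad": f.triad.ravel().tolist(),
            "base_identity": f.base_identity,
        }
        for f in frames
    ]
    text = json.dumps(records, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def frames_from_json(source) -> list[BasePairFrame]:
    """Read frames from a JSON string or file path."""
    if isinstance(source, str) and source.lstrip().startswith("["):
        records = json.loads(source)
    else:
        with open(source) as fh:
            records = json.load(fh)
    return [
        BasePairFrame(
            int(r["index"]),
            np.array(r["origin"], dtype=float),
            np.array(r["triad"], dtype=float).reshape(3, 3),
            r["base_identity"],
        )
        for r in records
    ]


def duplex_from_frames_json(source) -> DuplexModel:
    """Rebuild a DuplexModel from exported frames (user-supplied structures).

    Step rises/twists are recovered from consecutive frames: the rise is
    the axial projection of the origin step, the twist the in-plane
    rotation about the local z axis.
    """
    frames = frames_from_json(source)
    sequence = "".join(f.base_identity[0] for f in frames)
    rises, twists = [], []
    for f0, f1 in zip(frames[:-1], frames[1:]):
        rises.append(float((f1.origin - f0.origin) @ f0.triad[:, 2]))
        rel = f0.triad.T @ f1.triad
        twists.append(float(np.arctan2(rel[1, 0], rel[0, 0])))
    return DuplexModel(sequence, frames, np.array(rises), np.array(twists))


def write_av_xyz(av: AccessibleVolume, path, element: str = "He") -> None:
    """XYZ point cloud (Angstrom) for external viewers."""
    with open(path, "w") as fh:
        fh.write(f"{av.n_points}\n")
        fh.write(f"accessible volume, grid {av.grid_spacing} nm\n")
        for p in av.points:
            fh.write(f"{element} {10*p[0]:.3f} {10*p[1]:.3f} {10*p[2]:.3f}\n")


def write_av_json(av: AccessibleVolume, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "attachment_point_nm": av.attachment_point.tolist(),
                "grid_spacing_nm": av.grid_spacing,
                "points_nm": av.points.tolist(),
            },
            fh,
        )
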