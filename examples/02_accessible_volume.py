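"""Accessible volume of a tethered dye, exported for a molecular viewer.

Builds a 12-bp duplex, generates its atomic model, computes the AV of a
dye tethered at a backbone atom, and writes the point cloud as XYZ plus
the structure as PDB.
"""

import numpy as np

from dnafret import (
    AVParams,
    NanostructureModel,
    RigidPlacement,
    build_ideal_duplex,
    compute_accessible_volume,
    generate_atomic_model,
    mean_dye_position,
    write_pdb,
)
from dnafret.io import write_av_xyz

duplex = build_ideal_duplex("ACGTACGTACGT")
model = NanostructureModel({"d": duplex}, {"d": RigidPlacement()})
atomic = generate_atomic_model(model)
write_pdb(atomic, "duplex.pdb")

params = AVParams(linker_length=1.5, linker_width=0.45, dye_radius=0.35,
                  grid_spacing=0.1)
av = compute_accessible_volume(atomic, ("A", 6, "C5'"), params)
write_av_xyz(av, "av.xyz")

mp = mean_dye_position(av)
att = av.attachment_point
print(f"atomic model: {atomic.n_atoms} atoms -> duplex.pdb")
print(f"AV: {av.n_points} allowed positions at {params.grid_spacing} nm spacing -> av.xyz")
print(f"attachment point: ({att[0]:.2f}, {att[1]:.2f}, {att[2]:.2f}) nm")
print(f"mean dye position: ({mp[0]:.2f}, {mp[1]:.2f}, {mp[2]:.2f}) nm")
print(
    "\nThe mean position is displaced from the attachment atom away from\n"
    "the helix: the duplex excludes half the linker's reach, exactly the\n"
    "effect that makes AV-based dye placement matter for FRET distances."
)
print(f"displacement: {np.linalg.norm(mp - att):.2f} nm")
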