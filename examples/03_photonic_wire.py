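"""Intercalator-bridged photonic wire: transfer efficiency vs dye loading.

A 20-bp wire carries a PB donor and Cy3 acceptor at opposite termini;
YO-type intercalators loaded at random (nearest-neighbor exclusion,
geometry elongated/unwound per intercalation, density-dependent
photophysics) relay the exciton by homo-FRET.
"""

from dnafret import photonic_wire_fixture, wire_density_sweep
from dnafret.mechanics import StiffnessParams

wire = photonic_wire_fixture(n_bp=20).wire
densities = [0.0, 0.125, 0.25, 0.375, 0.5]

sweep = wire_density_sweep(wire, densities, n_patterns=300, seed=1)
print("rigid wire:")
print(sweep.to_string(index=False, float_format=lambda x: f"{x:.4f}"))

flex = wire_density_sweep(
    wire, [0.5], n_patterns=300, seed=1, stiffness=StiffnessParams()
)
print("\nthermally flexible wire at saturation (0.5 dyes/bp):")
print(flex.to_string(index=False, float_format=lambda x: f"{x:.4f}"))

print(
    "\nWithout intercalators the termini are ~6.5 nm apart and transfer is\n"
    "weak; loading builds a homo-FRET bridge and T rises steeply, then\n"
    "plateaus once the wire is fully connected.  Thermal flexibility\n"
    "barely changes the saturated efficiency: nearest-neighbor rates stay\n"
    "far above the recombination rate in every sampled conformation."
)
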