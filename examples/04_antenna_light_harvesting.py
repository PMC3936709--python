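"""Seven-helix bundle antennas: antenna effect, power, decay components.

Compares the 1:1:1 and 6:6:1 Py:Cy3:AF647 configurations: exciton
funneling efficiency into the AF647 acceptor, antenna effect (380 nm
donor excitation vs 620 nm direct acceptor excitation), power harvested
under reference sunlight, and the decay-associated lifetimes.
"""

from dnafret import (
    antenna_fixture,
    build_rate_matrix,
    decay_associated_spectra,
    initial_excitation,
    light_harvesting_report,
)
from dnafret.dyes import DipoleInstance

for kind in ("antenna_111", "antenna_661"):
    bundle = antenna_fixture(kind)
    system = bundle.system
    dipoles = [
        DipoleInstance(s.reference_position(), [0, 0, 1], s.species)
        for s in system.sites
    ]
    K = build_rate_matrix(
        dipoles,
        system.species_table,
        mode="dynamic",
        r0_overrides=system.r0_overrides,
        acceptor_ids=system.acceptor_ids,
    )
    report = light_harvesting_report(K, 380.0, 620.0)
    p0 = initial_excitation(K.species, 380.0)
    das = decay_associated_spectra(K, p0)
    fast = [
        f"{1000 * c.lifetime_ns:.0f}"
        for c in das
        if abs(c.amplitude) > 1e-6 and c.lifetime_ns < 0.5
    ]
    print(f"{bundle.metadata['stoichiometry']} antenna ({K.n} dyes):")
    print(f"  T(380 nm)          = {report.transfer_efficiency:.3f}")
    print(f"  antenna effect     = {report.antenna_effect:.3f}")
    print(f"  transferred power  = {report.transferred_power_w * 1e15:.4f} fW")
    print(f"  transfer components: {', '.join(fast)} ps")

print(
    "\nBoth designs funnel >90% of donor excitons into the acceptor, but\n"
    "the 6:6:1 antenna absorbs six times more light at 380 nm, so its\n"
    "antenna effect and harvested power are several-fold larger - the\n"
    "cross-section, not the transfer efficiency, is what the extra donors\n"
    "buy."
)
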