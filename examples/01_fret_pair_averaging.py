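"""Single FRET pair on a duplex: how conformational averaging changes T.

Builds an AF488-Cy5 pair separated by 10 bp, computes the tethered-dye
accessible volumes on the atomic model, and compares the mean-position,
isotropic (static positions, dynamic orientations) and fully static
averaging procedures.
"""

import numpy as np

from dnafret import fret_pair_fixture
from dnafret.averaging import AveragingMode, averaged_observable

bundle = fret_pair_fixture(separation_bp=10, tethered=True)
p0 = np.array([1.0, 0.0])  # donor excited

print("AF488 -> Cy5, 10 bp apart, R0 = 5.2 nm")
for site in bundle.system.sites:
    print(f"  {site.species}: AV of {site.av.n_points} grid points")

T_mp, _ = averaged_observable(bundle.system, AveragingMode("mean_position"), p0)
T_iso, se_iso = averaged_observable(
    bundle.system, AveragingMode("isotropic", n_samples=500, seed=1), p0
)
T_s, se_s = averaged_observable(
    bundle.system, AveragingMode("static_full", n_samples=500, seed=1), p0
)

print(f"mean-position T = {T_mp:.3f}")
print(f"isotropic     T = {T_iso:.3f} +- {se_iso:.3f}")
print(f"static        T = {T_s:.3f} +- {se_s:.3f}")
print(
    "\nThe mean-position value overestimates the transfer efficiency: the\n"
    "r^-6 coupling is convex, so averaging the observable over the dye\n"
    "position clouds (isotropic/static) gives the physically meaningful\n"
    "lower values, ordered mean-position > isotropic > static."
)
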