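# Methods

## Model overview

`dnafret` predicts optical and light-harvesting properties of
dye-functionalized DNA nanostructures in three stages: (i) a geometric
model of the DNA scaffold as rigid base-pair frames, (ii) placement of
dye transition dipoles relative to those frames, and (iii) incoherent
(Förster) exciton transport on the resulting dipole network.  Coherent
coupling, multi-exciton effects and photochemistry are out of scope: the
model assumes weak coupling (valid for inter-dye separations of roughly
2 nm and above; a warning is logged below ~1 nm) and the low-light,
single-exciton limit.

## Structure

A duplex is an ordered chain of base-pair frames: origin at the
base-pair center, z along the local helix axis, right-handed orthonormal
triad (a 3DNA-style convention, so reference atomic coordinates placed in
these frames are reproducible).  Successive frames are related by a step
transform; the ideal B-form step is a 0.34 nm rise along z and a
360/10.5 ≈ 34.29° twist about it, both overridable per step.
Intercalation modifies the occupied step by +0.34 nm of rise and a
configurable unwinding (default −16°; the exact values are dye-specific
and should be supplied per species when known).  Bundles are rigid
placements of ideally built duplexes; mechanical coupling at crossovers
is not modeled, so flexibility sampling applies per duplex.

Thermal ensembles treat each inter-bp step as a two-node beam element
with quadratic stretch/bend/twist energies and the B-form stiffness set
(stretch 1100 pN, bend 230 pN nm², twist 460 pN nm², default 298 K).
For a free rod these step energies are mechanically independent, so
drawing each step deviation from its Gaussian Boltzmann factor — e.g.
sd(twist) = √(k_BT·Δz/C) ≈ 3.2° per step — is *exact* normal-mode
sampling with k_BT/2 per mode; no finite-element relaxation is needed at
this scale.  Nonlinear lattice relaxation of scaffolded origami is not
implemented; such shapes enter through the frame-JSON import instead.

## Atomic model

Reference base-pair atom sets are placed rigidly at every frame and
written as standard PDB (Å on disk, nm in memory) via gemmi.  The
packaged references are **synthetic** idealized B-form coordinates built
from cylindrical geometry (phosphorus at 0.94 nm radius, C1′ at 0.59 nm,
C1′–C1′ 1.04 nm, ~10 atoms per nucleotide) — sufficient for steric
(accessible-volume) calculations and visualization, not crystallographic.
Users can substitute measured fragments with `load_reference_pdb`.  No
energy minimization or clash relief is attempted.

## Dye placement

Tethered dyes use the single-radius accessible-volume (AV1) algorithm: a
cubic grid (default 0.1 nm) around the attachment atom is classified by
two clearance criteria — the linker path needs linker_width/2 of room,
the dye sphere its full radius — and a grid point is allowed if the
shortest clash-free path from the attachment (26-neighbor Dijkstra, with
an exact straight-segment shortcut so unobstructed AVs are exact balls)
is no longer than the linker length.  When the attachment atom is inside
its own bonded-atom shell the path is seeded from the nearest path-clear
cells, as a real linker stub threads between bonded neighbors.  AV
points are unweighted; the AV3 (three-radius) union variant is provided
for ellipsoidal dyes.  Element van-der-Waals radii come from a small
packaged table (C 0.17, N 0.155, O 0.152, P 0.18, H 0.11 nm).

Intercalated and base-substituted dyes are fixed local frames: an offset
and unit orientation in a base-pair frame or in the mid-step frame
(mean of flanking origins, orientation at half the step twist).
Intercalator loading patterns are sampled uniformly among
nearest-neighbor-excluded occupancies (cap 0.5 dyes/bp) with the count
randomized between floor and ceiling of the target mean, so the realized
mean density is unbiased.

## Exciton transport

Pairwise rates follow k = (1/τ_D)(3κ²/2)(R₀,iso/r)⁶ with the isotropic
Förster radius R₀ = 0.02108·(κ²n⁻⁴Q_D J)^{1/6} nm (J in M⁻¹cm⁻¹nm⁴;
0.02108 nm is the standard 0.211 Å prefactor, and the implementation
checks it against the tabulated 8.79×10⁻⁵ Å⁶ form).  Spectral overlaps
use trapezoidal quadrature on the union wavelength grid; emission
spectra are normalized to unit area.  The refractive index defaults to
1.4 (aqueous biomolecular convention) and is configurable.  Literature
R₀ values can be supplied per ordered species pair, bypassing the
spectral route — the built-in fixtures do this for the well-established
pairs (AF488–Cy5 5.2 nm; Py→Cy3 3.7, Cy3→AF647 5.5, Py→AF647 3.3 nm).

The rate matrix K stores transfer j→i in entry (i,j) and closes each
column to −1/τ, so dp/dt = Kp loses population only through
recombination.  Integrated quantities use the exact identity
∫₀^∞ p dt = −K⁻¹p(0); transfer efficiency is the recombination at the
acceptor sites, T = Σ_a x_a/τ_a.  Transients use the eigendecomposition
(stiff BDF integration as fallback for defective matrices), which also
yields decay-associated spectra: mode m contributes
a_m v_{m,i}(Q_i/τ_i)F_i(λ), kept as signed arrays because rising
components have negative lobes.  A vectorized kinetic Monte-Carlo jump
simulation of single excitons provides an independent stochastic
estimate of T with binomial standard errors; solver and oracle agree
within 3 SE on randomized networks in the test suite.

## Conformational averaging

Because FRET observables are strongly non-linear in geometry, the
averaging order encodes the physics: `mean_position` (one solve at AV
centroids, κ²=2/3), `isotropic` (positions frozen per sample, dynamic
rotations → κ²=2/3, observable averaged — the default for tethered
dyes), `static_full` (positions and uniformly random orientations frozen,
explicit κ², observable averaged), `dynamic` (rates averaged over
positions, orientations analytic 2/3, then one solve) and `fixed_bp`
(dipoles at integer-rise anchor separations).  Static modes average the
observable; dynamic mode averages the rates.  The intermediate regime
(transfer comparable to rotational diffusion) has no automatic switch;
choose per system.  All sampling is seeded and reproducible.

## Optical properties

p(0) at an excitation wavelength is proportional to the per-dye molar
extinctions.  Assembly absorption is the extinction sum
(σ = 10³ln10·ε/N_A cm²); emission is Σ(Q_i/τ_i)·∫p_i dt·F_i(λ) and the
emitted photon count never exceeds the single absorbed exciton.  T(λ) is
computed by re-solving with the wavelength-dependent initial condition
on a configurable grid, giving σ_eff(λ)=σ(λ)T(λ) ≤ σ(λ).  Transferred
power is P = T_E ∫I(λ)σ(λ)T(λ)dλ, where the energy efficiency
T_E = T·(λ_D^em-peak/λ_A^em-peak) accounts for the Stokes losses between
donor absorption and acceptor emission; the peak-wavelength ratio is a
stated convention, overridable with a user-supplied energy ratio.  The
antenna effect AE = T·n_D ε_D(λ_exc)/ε_A(λ_A) assumes equal photon flux
for the two excitations and is exactly linear in n_D and T.  The default
"standard sunlight" irradiance is a smooth 5772 K blackbody curve scaled
to 1000 W m⁻² over 280–2500 nm — a synthetic, structureless stand-in
adequate for relative comparisons; supply tabulated data via CSV for
absolute numbers.

## Built-in model systems and what they do (and do not) show

The fixture generator emulates three published system classes: an
AF488–Cy5 FRET pair on a duplex, a PB → YO-intercalator → Cy3 photonic
wire (20/50-mer), and seven-helix-bundle antennas (1:1:1 and 6:6:1
Py:Cy3:AF647 with the printed inter-dye distances: 1.7/3.1/3.1 nm for
1:1:1; Cy3–AF 1.8–4.3 nm and Py–Cy3 1.5–2.4 nm spreads for 6:6:1).
All dye spectra are synthetic Gaussian bands with literature-style peak
positions, widths, extinctions, quantum yields and lifetimes, truncated
at 3σ (tabulated spectra have finite support; untruncated tails would
fabricate long-range overlap such as acceptor-to-bridge back transfer).
The YO intercalator carries a density-dependent (Q, τ) table emulating
self-quenching at high loading.  Passing tests on these fixtures
validates the *machinery* — geometry, rates, solver, averaging,
bookkeeping — and reproduces the qualitative physics (averaging-mode
ordering, wire saturation, antenna-effect scaling); absolute numbers for
real dyes require measured spectra and photophysics supplied through the
CSV/YAML interfaces.

On the wire fixture, transfer efficiency rises steeply with intercalator
density while the homo-FRET bridge forms and then saturates near 0.93;
past ~0.375 dyes/bp a sub-1% decline appears because back transfer from
the terminal acceptor into the bridge competes with acceptor
recombination.  The tests therefore assert a strict rise over the
connectivity regime and plateau-level behavior at saturation.

## Numerical choices

- Triads are re-orthonormalized (SVD) during frame chaining; the
  orthonormality invariant is held to 1e-9.
- Spectral quadrature is trapezoidal on merged grids with linear
  interpolation and zero extrapolation; synthetic bands carry explicit
  zero edges so union-grid integration cannot smear across band gaps.
- Eigen-solves fall back to stiff ODE integration when the eigenvector
  matrix is ill-conditioned (condition number > 1e12); DAS components
  are sorted by eigenvalue real part, slowest first.
- Problem sizes in the shipped analyses: 10⁶ orientation draws for the
  isotropic κ² average, 10⁵ kinetic Monte-Carlo trajectories, 10⁴
  sampled steps for thermal statistics, 1000 loading patterns per wire
  density, AV grids of 0.05–0.2 nm spacing.
- All randomness flows through seeded `numpy` generators; pipeline
  outputs embed the config hash, seed and package version.

## Known limitations

- No coherent/strong-coupling corrections; rates below ~1–2 nm
  separations are Förster-extrapolated and flagged, not corrected.
- AV dyes have no orientation potential (uniform positions, isotropic or
  uniformly random orientations); MD- or anisotropy-derived
  distributions are not modeled.
- Bundle helices are mechanically independent; crossover constraints and
  large-deformation origami shapes must be imported as frames.
- The energy-efficiency convention (emission-peak ratio) is a
  simplification of full spectral energy bookkeeping.
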