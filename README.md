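# dnafret

Structure-based prediction of FRET exciton transport and light-harvesting
properties of dye-functionalized DNA nanostructures.

DNA self-assembly can place chromophores at programmed positions and
orientations in 3D, turning duplexes, bundles and origami into photonic
wires and artificial light-harvesting antennas.  Whether such a design
works depends sensitively on nanometer-scale inter-dye geometry: Förster
transfer rates scale as r⁻⁶ and depend on the mutual dipole orientation.
`dnafret` models the chain from structure to optics:

1. **Structure** — duplexes and multi-helix bundles as chains of rigid
   base-pair frames (origin + orthonormal triad, 0.34 nm/bp rise,
   10.5 bp/turn), with intercalator-induced elongation/unwinding and
   thermal conformational ensembles sampled from elastic-rod mechanics
   (stretch 1100 pN, bend 230 pN nm², twist 460 pN nm²).
2. **Atoms & dyes** — atomic models from reference base pairs placed at
   each frame (PDB export); tethered dyes placed by the accessible-volume
   (AV) algorithm (grid flood-fill limited by linker length and dye
   radius), intercalated/base-substituted dyes as fixed local frames.
3. **Exciton transport** — dyes as point transition dipoles coupled by
   pairwise FRET rates

   k_ij = (1/τ_i) · (3κ²/2) · (R₀,ij / r_ij)⁶,  R₀ = 0.02108 · (κ² n⁻⁴ Q_D J)^{1/6} nm

   assembled into the master-equation generator **K** (column sums −1/τ);
   transfer efficiency from the exact identity ∫p dt = −K⁻¹p(0); decay-
   associated spectra from the eigenmodes of **K**; a kinetic Monte-Carlo
   jump simulation as an independent stochastic cross-check.
4. **Optics** — wavelength-resolved transfer efficiency T(λ), assembly
   absorption/emission spectra, effective cross-section σ_eff = σ·T,
   power transferred to the acceptors under a spectral irradiance, and
   the antenna effect AE = T · n_D ε_D(λ_exc)/ε_A(λ_A).

Conformational averaging follows the timescale hierarchy of dye motion:
mean-position, isotropic (static positions, dynamic orientations, κ²=2/3),
fully static (explicit κ² per sample) and dynamic (rate-averaged) modes
are all provided, and structural thermal ensembles compose with them.

## Worked example

`examples/04_antenna_light_harvesting.py` evaluates two seven-helix-bundle
antenna designs in which pyrene donors funnel excitons into a single
AF647 acceptor through Cy3 bridges (R₀: Py→Cy3 3.7 nm, Cy3→AF 5.5 nm,
Py→AF 3.3 nm; donor excitation 380 nm, direct-acceptor readout 620 nm):

```
1:1:1 antenna (3 dyes):
  T(380 nm)          = 0.951
  antenna effect     = 0.250
  transferred power  = 0.0079 fW
  transfer components: 31, 14 ps
6:6:1 antenna (13 dyes):
  T(380 nm)          = 0.898
  antenna effect     = 1.417
  transferred power  = 0.0210 fW
  transfer components: 75, 54, 37, 29, 28, 19, 11, 11, 8, 6, 4, 1 ps
```

Both designs transfer >90% of donor excitons to the acceptor (picosecond
transfer components against nanosecond recombination); the 6:6:1 antenna
wins on light harvesting because six donors absorb six times more light —
its antenna effect and harvested power under reference sunlight are
several-fold larger.  The other examples cover AV placement, averaging-
mode comparisons for a single FRET pair, an intercalator photonic wire,
and thermal ensembles.

A thin CLI mirrors the library (`dnafret fixture / build / atomic / av /
rates / simulate / spectra / sweep / report`); every run emits a
`results.json` with the config hash, seed and version for reproducibility.

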