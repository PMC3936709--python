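"""Thermal conformational ensembles of duplexes from elastic-rod mechanics.

dsDNA is treated as a homogeneous isotropic elastic rod discretized at
base-pair resolution: each inter-bp step is a two-node beam element with
quadratic stretch, bend and twist energies in the deviations from the
ground-state step geometry.  Because the steps of a free (unconstrained)
rod are mechanically independent, the Boltzmann distribution of the
quadratic energy factorizes into independent Gaussians per step degree
of freedom — sampling them directly is exact normal-mode sampling, with
each mode carrying k_BT/2 of mean energy by equipartition.

Default stiffnesses are the B-form values used throughout the framework:
stretch 1100 pN, bend 230 pN nm^2, twist 460 pN nm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DuplexModel, NanostructureModel, frames_from_steps

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "StiffnessParams",
    "ConformationalEnsemble",
    "draw_step_deviations",
    "sample_thermal_ensemble",
]

#: Boltzmann constant in pN nm / K
BOLTZMANN_PN_NM_PER_K = 1.380649e-2


@dataclass(frozen=True)
class StiffnessParams:
    """Elastic-rod stiffnesses of B-form dsDNA.

    stretch [pN], bend and twist [pN nm^2], temperature [K].
    """

    stretch: float = 1100.0
    bend: float = 230.0
    twist: float = 460.0
    temperature: float = 298.0

    def __post_init__(self):
        if min(self.stretch, self.bend, self.twist, self.temperature) <= 0:
            raise ValueError("stiffnesses and temperature must be positive")

    @property
    def kBT(self) -> float:
        return BOLTZMANN_PN_NM_PER_K * self.temperature


@dataclass
class ConformationalEnsemble:
    """Boltzmann-weighted snapshots of a nanostructure model."""

    samples: list[NanostructureModel]
    seed: int
    temperature: float

    def __len__(self) -> int:
        return len(self.samples)


def draw_step_deviations(
    rises: np.ndarray,
    stiff: StiffnessParams,
    n_samples: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw Gaussian step deviations for a chain with ground-state step
    rises ``rises`` (nm).

    Per step of length dz the harmonic energies are S/(2 dz) * dl^2,
    B/(2 dz) * beta^2 (two bending directions) and C/(2 dz) * dtheta^2,
    giving Boltzmann variances kBT dz / S, kBT dz / B and kBT dz / C.

    Returns arrays of shape (n_samples, n_steps[, 2]) keyed by
    ``stretch`` (nm), ``bend`` (rad, two directions) and ``twist`` (rad).
    """
    kBT = stiff.kBT
    n_steps = len(rises)
    sd_stretch = np.sqrt(kBT * rises / stiff.stretch)
    sd_bend = np.sqrt(kBT * rises / stiff.bend)
    sd_twist = np.sqrt(kBT * rises / stiff.twist)
    return {
        "stretch": rng.normal(0.0, 1.0, (n_samples, n_steps)) * sd_stretch,
        "bend": rng.normal(0.0, 1.0, (n_samples, n_steps, 2)) * sd_bend[:, None],
        "twist": rng.normal(0.0, 1.0, (n_samples, n_steps)) * sd_twist,
    }


def deviation_energies(
    deviations: dict[str, np.ndarray], rises: np.ndarray, stiff: StiffnessParams
) -> np.ndarray:
    """Elastic energy (pN nm) per sample and per scalar degree of freedom.

    Shape (n_samples, 4 * n_steps): stretch, twist and the two bend
    directions of every step.  Equipartition puts kBT/2 in each column.
    """
    e_stretch = 0.5 * stiff.stretch / rises * deviations["stretch"] ** 2
    e_twist = 0.5 * stiff.twist / rises * deviations["twist"] ** 2
    e_bend = 0.5 * stiff.bend / rises[:, None] * deviations["bend"] ** 2
    return np.concatenate(
        [e_stretch, e_twist, e_bend[:, :, 0], e_bend[:, :, 1]], axis=1
    )


def _deform_duplex(duplex: DuplexModel, dev, sample: int) -> DuplexModel:
    rises = duplex.step_rises + dev["stretch"][sample]
    twists = duplex.step_twists + dev["twist"][sample]
    bends = dev["bend"][sample]
    frames = frames_from_steps(duplex.sequence, rises, twists, bends)
    return DuplexModel(
        duplex.sequence, frames, rises, twists, duplex.intercalation_sites
    )


def sample_thermal_ensemble(
    model: NanostructureModel,
    stiff: StiffnessParams | None = None,
    n_samples: int = 100,
    seed: int = 0,
) -> ConformationalEnsemble:
    """Sample the thermal ensemble of a nanostructure.

    Each duplex deforms independently with per-step Gaussian stretch,
    bend and twist deviations drawn from the Boltzmann distribution of
    the elastic-rod energy; rigid placements are kept fixed (crossover
    coupling between bundle helices is not modeled).  Deterministic
    under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    stiff = stiff or StiffnessParams()
    rng = np.random.default_rng(seed)
    per_duplex = {
        ident: draw_step_deviations(dup.step_rises, stiff, n_samples, rng)
        for ident, dup in model.duplexes.items()
    }
    samples = []
    for s in range(n_samples):
        duplexes = {
            ident: _deform_duplex(dup, per_duplex[ident], s)
            for ident, dup in model.duplexes.items()
        }
        samples.append(NanostructureModel(duplexes, dict(model.placements)))
    return ConformationalEnsemble(samples, seed, stiff.temperature)
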