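"""Conformational averaging of FRET observables over dye distributions.

FRET observables are strongly non-linear in dye position and orientation,
so the order of averaging matters.  The modes implemented here mirror the
physically distinct timescale regimes:

- ``mean_position``: one solve with every dye at its AV centroid (or fixed
  position), dynamic rotational averaging (kappa^2 = 2/3).
- ``isotropic``: static translational averaging (positions drawn from the
  AVs, observable averaged over samples) with dynamic rotational
  averaging per sample.  The default for tethered dyes.
- ``static_full``: positions and orientations both frozen during
  transfer; orientations drawn uniformly on the sphere for AV dyes,
  geometric kappa^2 evaluated explicitly, observable averaged.
- ``dynamic``: rates averaged over the positional distribution first
  (orientations contribute the analytic kappa^2 = 2/3), then a single
  solve of the averaged rate matrix.
- ``fixed_bp``: dyes at their anchor positions separated by integer
  multiples of the axial rise, kappa^2 = 2/3 (no AV displacement).

Static modes average the OBSERVABLE over samples; dynamic mode averages
the RATES.  All sampling is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accessible_volume import AccessibleVolume, mean_dye_position
from .dyes import DipoleInstance
from .photophysics import DyeSpecies, RateMatrix, build_rate_matrix
from .dynamics import integrated_populations, transfer_efficiency

__all__ = ["AveragingMode", "DyeSite", "DyeSystem", "averaged_observable"]

_MODES = ("mean_position", "isotropic", "static_full", "dynamic", "fixed_bp")


@dataclass(frozen=True)
class AveragingMode:
    """Averaging mode selector with sample count and seed."""

    mode: str = "isotropic"
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class DyeSite:
    """One dye site: a species plus either an AV (tethered dye) or a fixed
    position/orientation (intercalated, base-substituted, or anchor point)."""

    species: str
    av: AccessibleVolume | None = None
    position: np.ndarray | None = None
    orientation: np.ndarray | None = None

    def __post_init__(self):
        if self.av is None and self.position is None:
            raise ValueError("site needs an accessible volume or a fixed position")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            self.orientation = self.orientation / np.linalg.norm(self.orientation)

    @property
    def is_tethered(self) -> bool:
        return self.av is not None

    def reference_position(self) -> np.ndarray:
        return mean_dye_position(self.av) if self.is_tethered else self.position


@dataclass
class DyeSystem:
    """A set of dye sites with shared photophysics and acceptor definition."""

    sites: list[DyeSite]
    species_table: dict[str, DyeSpecies]
    acceptor_ids: tuple[int, ...]
    n_medium: float = 1.4
    r0_overrides: dict = field(default_factory=dict)

    def species_list(self) -> list[DyeSpecies]:
        return [self.species_table[s.species] for s in self.sites]


def _uniform_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _dipoles(system: DyeSystem, positions, orientations) -> list[DipoleInstance]:
    return [
        DipoleInstance(p, o, site.species)
        for p, o, site in zip(positions, orientations, system.sites)
    ]


def _default_orientations(system: DyeSystem) -> list[np.ndarray]:
    return [
        s.orientation if s.orientation is not None else np.array([0.0, 0.0, 1.0])
        for s in system.sites
    ]


def _build(system: DyeSystem, positions, orientations, mode: str) -> RateMatrix:
    return build_rate_matrix(
        _dipoles(system, positions, orientations),
        system.species_table,
        n_medium=system.n_medium,
        mode=mode,
        r0_overrides=system.r0_overrides,
        acceptor_ids=system.acceptor_ids,
    )


def _evaluate(K: RateMatrix, p0, observable):
    if callable(observable):
        return observable(K, p0)
    if observable == "T":
        return transfer_efficiency(K, p0)
    if observable == "populations":
        return integrated_populations(K, p0)
    raise ValueError("observable must be 'T', 'populations' or a callable(K, p0)")


def _sample_positions(system: DyeSystem, rng: np.random.Generator) -> list[np.ndarray]:
    out = []
    for site in system.sites:
        if site.is_tethered:
            out.append(site.av.points[rng.integers(0, site.av.n_points)])
        else:
            out.append(site.position)
    return out


def averaged_observable(
    system: DyeSystem,
    mode: AveragingMode,
    p0,
    observable="T",
):
    """Average a FRET observable over the dye conformational distribution.

    Returns ``(mean, standard_error)``; the standard error is None for the
    single-solve modes (mean_position, dynamic, fixed_bp).
    """
    rng = np.random.default_rng(mode.seed)
    orients = _default_orientations(system)

    if mode.mode in ("mean_position", "fixed_bp"):
        positions = [s.reference_position() for s in system.sites]
        K = _build(system, positions, orients, "dynamic")
        return _evaluate(K, p0, observable), None

    if mode.mode == "isotropic":
        vals = []
        for _ in range(mode.n_samples):
            K = _build(system, _sample_positions(system, rng), orients, "dynamic")
            vals.append(_evaluate(K, p0, observable))
        vals = np.asarray(vals, dtype=float)
        return vals.mean(axis=0), vals.std(axis=0, ddof=1) / np.sqrt(len(vals))

    if mode.mode == "static_full":
        vals = []
        for _ in range(mode.n_samples):
            positions = _sample_positions(system, rng)
            sample_orients = [
                _uniform_unit_vectors(rng, 1)[0] if s.is_tethered else o
                for s, o in zip(system.sites, orients)
            ]
            K = _build(system, positions, sample_orients, "static")
            vals.append(_evaluate(K, p0, observable))
        vals = np.asarray(vals, dtype=float)
        return vals.mean(axis=0), vals.std(axis=0, ddof=1) / np.sqrt(len(vals))

    # dynamic: average the rate matrix itself over the positional
    # distribution; the fully sampled orientational average is the
    # analytic kappa^2 = 2/3
    mats = []
    template = None
    for _ in range(mode.n_samples):
        K = _build(system, _sample_positions(system, rng), orients, "dynamic")
        template = K
        mats.append(K.K)
    mean_K = np.mean(mats, axis=0)
    # re-close the columns: averaging preserves the -1/tau column sums, but
    # enforce it exactly against accumulated roundoff
    for i in range(mean_K.shape[0]):
        off = np.sum(mean_K[:, i]) - mean_K[i, i]
        mean_K[i, i] = -1.0 / template.species[i].lifetime_ns - off
    K = RateMatrix(mean_K, template.species, system.acceptor_ids, system.n_medium)
    return _evaluate(K, p0, observable), None
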