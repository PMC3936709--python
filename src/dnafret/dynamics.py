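"""Master-equation exciton dynamics.

The exciton population p(t) of an n-dye system evolves as dp/dt = K p
with the rate matrix K of :mod:`dnafret.photophysics` (single-exciton,
low-light limit: sum p(0) = 1).  Transient solutions come from the
eigendecomposition p(t) = sum_m a_m v_m exp(lambda_m t); integrated
(steady-state-equivalent) quantities come from the exact linear-solve
identity int_0^inf p dt = -K^{-1} p(0), so the transfer efficiency

    T = sum_{a in acceptors} (1/tau_a) [ -K^{-1} p0 ]_a

involves no time discretization.  A kinetic Monte-Carlo jump simulation
of single excitons serves as an independent stochastic cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .photophysics import DyeSpecies, RateMatrix

__all__ = [
    "ExcitonState",
    "DASComponent",
    "solve_transient",
    "integrated_populations",
    "transfer_efficiency",
    "kmc_transfer_efficiency",
    "decay_associated_spectra",
]

log = logging.getLogger(__name__)

_EIG_RESIDUAL_TOL = 1e-8


@dataclass
class ExcitonState:
    """Transient populations: times [ns] and p[i, t] per dye."""

    times: np.ndarray
    populations: np.ndarray  # (n_dyes, n_times)
    p0: np.ndarray

    def total(self) -> np.ndarray:
        return self.populations.sum(axis=0)


@dataclass
class DASComponent:
    """One eigenmode of K: decay eigenvalue, amplitude, eigenvector and the
    (signed) emission spectrum associated with the decay.  Negative lobes
    mark populations that rise rather than decay in that mode, so the
    spectrum is kept as raw signed arrays."""

    eigenvalue: float  # ns^-1, negative
    amplitude: float
    eigenvector: np.ndarray
    wavelengths: np.ndarray
    spectrum_values: np.ndarray

    @property
    def lifetime_ns(self) -> float:
        return -1.0 / self.eigenvalue


def _check_p0(K: np.ndarray, p0) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (K.shape[0],):
        raise ValueError("p0 must match the rate-matrix dimension")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("initial exciton population must sum to 1")
    if np.any(p0 < -1e-12):
        raise ValueError("initial populations must be non-negative")
    return p0


def _eigendecompose(K: np.ndarray):
    lam, V = np.linalg.eig(K)
    if np.linalg.cond(V) > 1e12:
        return None
    return lam, V


def solve_transient(K: RateMatrix | np.ndarray, p0, times) -> ExcitonState:
    """Solve dp/dt = K p on the given time grid [ns].

    Uses the eigendecomposition of K; falls back to stiff ODE integration
    when K is defective (degenerate eigenvalues without a full eigenbasis).
    """
    Kmat = K.K if isinstance(K, RateMatrix) else np.asarray(K, dtype=float)
    p0 = _check_p0(Kmat, p0)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    eig = _eigendecompose(Kmat)
    if eig is not None:
        lam, V = eig
        a = np.linalg.solve(V, p0.astype(complex))
        p = np.real(V @ (a[:, None] * np.exp(lam[:, None] * times[None, :])))
    else:
        log.info("rate matrix is defective; falling back to stiff ODE integration")
        sol = solve_ivp(
            lambda t, y: Kmat @ y,
            (0.0, float(times[-1])),
            p0,
            t_eval=times,
            method="BDF",
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"ODE fallback failed: {sol.message}")
        p = sol.y
    return ExcitonState(times, np.clip(p, 0.0, None), p0)


def integrated_populations(K: RateMatrix | np.ndarray, p0) -> np.ndarray:
    """Exact time-integrated populations int_0^inf p_i dt [ns]: solves
    K x = -p0 (K is Hurwitz-stable whenever every dye has a finite
    lifetime, so the system is well posed)."""
    Kmat = K.K if isinstance(K, RateMatrix) else np.asarray(K, dtype=float)
    p0 = _check_p0(Kmat, p0)
    try:
        return np.linalg.solve(Kmat, -p0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "rate matrix is singular: some dye has no relaxation pathway"
        ) from exc


def transfer_efficiency(K: RateMatrix, p0, acceptor_ids=None) -> float:
    """Fraction of the initial exciton population that recombines
    (radiatively or not) at the acceptor sites."""
    acceptors = tuple(acceptor_ids) if acceptor_ids is not None else K.acceptor_ids
    if not acceptors:
        raise ValueError("acceptor_ids must be a non-empty subset of sites")
    if any(not 0 <= a < K.n for a in acceptors):
        raise ValueError(f"unknown acceptor id in {acceptors}")
    x = integrated_populations(K, p0)
    tau = K.lifetimes
    return float(sum(x[a] / tau[a] for a in acceptors))


def kmc_transfer_efficiency(
    K: RateMatrix, p0, n_traj: int = 10**5, seed: int = 0
) -> tuple[float, float]:
    """Kinetic Monte-Carlo estimate of the transfer efficiency.

    Simulates ``n_traj`` independent single-exciton jump trajectories:
    from dye i the exciton hops to j with rate K[j, i] or recombines with
    rate 1/tau_i; the estimate is the fraction recombining at acceptor
    sites.  Returns (T_hat, standard_error).  Independent of the linear
    solver, so it serves as a stochastic oracle for it.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    p0 = _check_p0(K.K, p0)
    rng = np.random.default_rng(seed)
    n = K.n
    tau = K.lifetimes
    # embedded jump chain: from state i, P(next) over n hops + 1 recombination
    probs = np.zeros((n, n + 1))
    for i in range(n):
        hop = K.K[:, i].copy()
        hop[i] = 0.0
        total = hop.sum() + 1.0 / tau[i]
        probs[i, :n] = hop / total
        probs[i, n] = (1.0 / tau[i]) / total
    cum = np.cumsum(probs, axis=1)
    state = rng.choice(n, size=n_traj, p=p0)
    absorbed_at = np.full(n_traj, -1, dtype=int)
    active = np.arange(n_traj)
    while active.size:
        u = rng.random(active.size)
        nxt = (u[:, None] > cum[state[active]]).sum(axis=1)
        recombined = nxt == n
        absorbed_at[active[recombined]] = state[active[recombined]]
        hopping = ~recombined
        state[active[hopping]] = nxt[hopping]
        active = active[hopping]
    acceptors = np.array(K.acceptor_ids, dtype=int)
    hits = np.isin(absorbed_at, acceptors)
    t_hat = float(hits.mean())
    se = float(np.sqrt(max(t_hat * (1.0 - t_hat), 1e-30) / n_traj))
    return t_hat, se


def decay_associated_spectra(
    K: RateMatrix, p0, species: list[DyeSpecies] | None = None
) -> list[DASComponent]:
    """Eigenmode decomposition of the decay with per-mode emission spectra.

    p(t) = sum_m a_m v_m exp(lambda_m t); the spectrum of mode m is
    sum_i a_m v_{m,i} (Q_i / tau_i) F_i(lambda) on the union emission
    grid.  Components are sorted by eigenvalue real part descending
    (slowest decay first).  Requires a diagonalizable K; for sampled
    conformations compute DAS at the mean dye positions instead.
    """
    p0 = _check_p0(K.K, p0)
    species = species if species is not None else K.species
    eig = _eigendecompose(K.K)
    if eig is None:
        raise np.linalg.LinAlgError(
            "rate matrix is defective (no full eigenbasis); compute DAS from "
            "mean dye positions rather than a degenerate sampled configuration"
        )
    lam, V = eig
    a = np.linalg.solve(V, p0.astype(complex))
    residual = np.linalg.norm((V @ a).real - p0)
    if residual > _EIG_RESIDUAL_TOL:
        raise np.linalg.LinAlgError("eigenmode reconstruction of p(0) failed")
    order = np.argsort(-lam.real)
    grid = np.unique(np.concatenate([s.emission.wavelengths for s in species]))
    emission_rows = np.array(
        [s.quantum_yield / s.lifetime_ns * s.emission.value_at(grid) for s in species]
    )
    components = []
    for m in order:
        weights = (a[m] * V[:, m]).real
        spec_vals = weights @ emission_rows
        components.append(
            DASComponent(
                float(lam[m].real),
                float(a[m].real),
                V[:, m].real,
                grid,
                spec_vals,
            )
        )
    return components
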