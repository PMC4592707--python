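"""Discretized-action machinery: the boundary-value path optimizer.

A path {q_j}, j = 0..P, with fixed endpoints and time increment Δ has the
discretized action

    S = Σ_{j=0}^{P−1} L_j Δ,
    L_j = Σ_I m_I / (2Δ²) |q_{I,j} − q_{I,j+1}|² − V(q_j),

whose stationary points are discrete Newtonian trajectories.  Because plain
action extremization does not fix the energy of the trajectory, the working
objective adds a total-energy-conservation penalty

    Θ = S + μ Σ_{j=0}^{P−1} (E_j − E_target)²,
    E_j = K_j + V(q_j),   K_j = Σ_I m_I/(2Δ²) |q_{I,j} − q_{I,j+1}|²,

so minimizing Θ over the interior frames yields a smooth trajectory that
both satisfies the discrete stationarity condition and conserves total
energy near ``E_target``.  An optional outer loop ("annealing") lowers
``E_target`` toward the smallest value that still admits a conserving path,
which is how the lowest-potential-energy-barrier pathway between the two
end states is located.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _sp_minimize

from .structures import Path

__all__ = [
    "ActionParams", "ActionValue", "ConvergenceReport", "RunResult",
    "EnsembleResult", "ActionDivergenceError",
    "discretized_action", "action_gradient", "init_trial_path",
    "minimize_action", "pathway_barrier", "run_ensemble",
]


class ActionDivergenceError(RuntimeError):
    """The penalized action became non-finite during optimization."""


@dataclass
class ActionParams:
    """Knobs of the discretized-action objective and its optimizer.

    ``n_segments`` is P (the path has P+1 frames); ``delta_t`` is the reduced
    time increment Δ; ``penalty_weight`` is μ of the energy-conservation
    term; ``target_energy`` is E_target (``None`` → max of the endpoint
    potential energies plus ``target_margin``).  ``anneal_rounds`` > 0
    re-optimizes with E_target lowered to the current path's peak potential
    energy plus ``anneal_offset``, seeking the lowest-barrier pathway.
    """

    n_segments: int = 100
    delta_t: float = 1.0
    penalty_weight: float = 1.0
    target_energy: float | None = None
    target_margin: float = 0.0
    seed: int = 0
    max_iterations: int = 5000
    gradient_tolerance: float = 1e-6
    noise_amplitude: float = 0.5
    init_mode: str = "interpolate+noise"   # or "random"
    anneal_rounds: int = 0
    anneal_offset: float = 0.0

    def __post_init__(self):
        if self.n_segments < 2:
            raise ValueError("n_segments (P) must be >= 2")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight (mu) must be >= 0")


@dataclass
class ActionValue:
    """Decomposition of the penalized action for one path."""

    total_action: float
    per_frame_lagrangian: np.ndarray   # L_j, j = 0..P-1
    kinetic_part: float                # Σ K_j Δ
    potential_part: float              # Σ V_j Δ
    penalty_part: float                # μ Σ (E_j − E_target)²
    segment_energies: np.ndarray       # E_j = K_j + V_j, j = 0..P-1
    target_energy: float


def _masses_bcast(path: Path) -> np.ndarray:
    return path.topology.masses[None, :, None]


def _kinetic_per_segment(coords: np.ndarray, masses: np.ndarray,
                         delta_t: float) -> np.ndarray:
    diff = coords[:-1] - coords[1:]
    return np.sum(masses * diff * diff, axis=(1, 2)) / (2.0 * delta_t ** 2)


def _resolve_target(params: ActionParams, potential, path: Path) -> float:
    if params.target_energy is not None:
        return float(params.target_energy)
    v0 = potential.energy(path.coords[0])
    vP = potential.energy(path.coords[-1])
    return max(v0, vP) + params.target_margin


def discretized_action(path: Path, potential, params: ActionParams) -> ActionValue:
    """Evaluate S (and the conservation penalty) on a path.

    S = Σ_{j<P} L_j Δ with L_j the kinetic term of segment j minus V(q_j);
    ``total_action`` includes the penalty when μ > 0.
    """
    if path.n_segments != params.n_segments:
        raise ValueError(
            f"path has P={path.n_segments}, params expect P={params.n_segments}")
    dt = params.delta_t
    masses = path.topology.masses[None, :, None]
    K = _kinetic_per_segment(path.coords, masses, dt)           # (P,)
    V = potential.energy_many(path.coords[:-1])                 # V(q_j), j<P
    L = K - V
    S = float(L.sum() * dt)
    E = K + V
    e_target = _resolve_target(params, potential, path)
    penalty = float(params.penalty_weight * np.sum((E - e_target) ** 2))
    total = S + (penalty if params.penalty_weight > 0 else 0.0)
    return ActionValue(
        total_action=total,
        per_frame_lagrangian=L,
        kinetic_part=float(K.sum() * dt),
        potential_part=float(V.sum() * dt),
        penalty_part=penalty,
        segment_energies=E,
        target_energy=e_target,
    )


def action_gradient(path: Path, potential, params: ActionParams) -> np.ndarray:
    """Analytic gradient of the penalized action w.r.t. interior frames.

    Returns shape (P−1, N, 3); endpoint frames receive no entries (they are
    fixed boundary data).
    """
    if path.n_segments != params.n_segments:
        raise ValueError("path/params P mismatch")
    dt = params.delta_t
    mu = params.penalty_weight
    coords = path.coords
    masses = path.topology.masses[None, :, None]
    P = path.n_segments

    K = _kinetic_per_segment(coords, masses, dt)
    V = potential.energy_many(coords[:-1])
    gradV = potential.gradient_many(coords[1:P])   # ∇V(q_k), k = 1..P−1
    E = K + V
    e_target = _resolve_target(params, potential, path)

    m_over = masses / dt ** 2
    q = coords
    # dS/dq_k = Δ [ m/Δ² (2 q_k − q_{k−1} − q_{k+1}) − ∇V(q_k) ], k = 1..P−1
    lap = 2 * q[1:P] - q[0:P - 1] - q[2:P + 1]
    grad = dt * (m_over * lap - gradV)

    if mu > 0:
        dev = 2.0 * mu * (E - e_target)            # (P,)
        # K_{k−1} depends on q_k via m/Δ²(q_k − q_{k−1}); K_k via m/Δ²(q_k − q_{k+1})
        grad += dev[0:P - 1, None, None] * m_over * (q[1:P] - q[0:P - 1])
        grad += dev[1:P, None, None] * (m_over * (q[1:P] - q[2:P + 1]) + gradV)
    return grad


def init_trial_path(endpoints, params: ActionParams,
                    delta_t: float | None = None) -> Path:
    """Seeded trial path between two fixed endpoints.

    Interior frames are the linear interpolant plus i.i.d. Gaussian
    displacements of standard deviation ``noise_amplitude`` per Cartesian
    component (``init_mode="random"`` replaces the interpolant mean with
    uniform random points in the endpoints' bounding box, the fully random
    historical initialization).  Identical seed ⇒ bit-identical path;
    frames 0 and P equal the endpoints exactly.
    """
    a, b = endpoints
    if a.topology.n_atoms != b.topology.n_atoms:
        raise ValueError("endpoints must share one topology")
    P = params.n_segments
    rng = np.random.default_rng(params.seed)
    frac = np.arange(P + 1)[:, None, None] / P
    coords = (1 - frac) * a.positions[None] + frac * b.positions[None]
    if params.init_mode == "random":
        lo = np.minimum(a.positions, b.positions).min(axis=0)
        hi = np.maximum(a.positions, b.positions).max(axis=0)
        coords[1:P] = rng.uniform(lo, hi, size=coords[1:P].shape)
    if params.noise_amplitude > 0:
        coords[1:P] += rng.normal(
            0.0, params.noise_amplitude, size=coords[1:P].shape)
    coords[0] = a.positions
    coords[P] = b.positions
    return Path(coords, a.topology,
                delta_t=params.delta_t if delta_t is None else delta_t)


@dataclass
class ConvergenceReport:
    converged: bool
    n_iterations: int
    final_grad_norm: float
    final_action: float
    initial_action: float
    target_energy: float
    message: str = ""
    action_history: list = field(default_factory=list)


def minimize_action(path: Path, potential, params: ActionParams):
    """Minimize the penalized action over the interior frames (L-BFGS).

    Returns ``(Path, ConvergenceReport)``.  Endpoints are bit-identical to
    the input's; the objective is non-increasing over accepted iterates.
    Non-finite action raises :class:`ActionDivergenceError` with diagnostics.
    """
    P = path.n_segments
    e_target = _resolve_target(params, potential, path)
    prm = replace(params, target_energy=e_target)
    topo = path.topology
    dt = prm.delta_t
    q0 = path.coords[0].copy()
    qP = path.coords[P].copy()
    shape = (P - 1,) + path.coords.shape[1:]

    def assemble(x):
        coords = np.empty_like(path.coords)
        coords[0] = q0
        coords[P] = qP
        coords[1:P] = x.reshape(shape)
        return Path(coords, topo, delta_t=dt)

    history = []
    last = [np.nan]
    masses = topo.masses[None, :, None]
    m_over = masses / dt ** 2
    mu = prm.penalty_weight

    def fun(x):
        # Fused Θ and ∇Θ: one batched potential evaluation per step.
        q = np.empty_like(path.coords)
        q[0], q[P] = q0, qP
        q[1:P] = x.reshape(shape)
        V, gradV_all = potential.energy_gradient_many(q[:-1])
        K = _kinetic_per_segment(q, masses, dt)
        E = K + V
        theta = float((K - V).sum() * dt)
        if mu > 0:
            theta += float(mu * np.sum((E - e_target) ** 2))
        if not np.isfinite(theta):
            raise ActionDivergenceError(
                f"non-finite action at iteration {len(history)} "
                f"(K sum={K.sum():.3g}, V sum={V.sum():.3g})")
        lap = 2 * q[1:P] - q[0:P - 1] - q[2:P + 1]
        grad = dt * (m_over * lap - gradV_all[1:P])
        if mu > 0:
            dev = 2.0 * mu * (E - e_target)
            grad += dev[0:P - 1, None, None] * m_over * (q[1:P] - q[0:P - 1])
            grad += dev[1:P, None, None] * (m_over * (q[1:P] - q[2:P + 1])
                                            + gradV_all[1:P])
        last[0] = theta
        return theta, grad.ravel()

    def cb(xk):
        history.append(last[0])

    x0 = path.coords[1:P].ravel().copy()
    a0 = discretized_action(path, potential, prm).total_action
    res = _sp_minimize(
        fun, x0, jac=True, method="L-BFGS-B", callback=cb,
        options={"maxiter": params.max_iterations,
                 "gtol": params.gradient_tolerance,
                 "ftol": 1e-16, "maxfun": 20 * params.max_iterations},
    )
    out = assemble(res.x)
    gnorm = float(np.max(np.abs(action_gradient(out, potential, prm))))
    report = ConvergenceReport(
        converged=bool(gnorm <= params.gradient_tolerance or res.success),
        n_iterations=int(res.nit),
        final_grad_norm=gnorm,
        final_action=float(res.fun),
        initial_action=float(a0),
        target_energy=e_target,
        message=str(res.message),
        action_history=history,
    )
    return out, report


def pathway_barrier(path: Path, potential):
    """Potential-energy barrier of a path: max_j V(q_j) − V(q_0).

    Returns ``(barrier, frame_index)``; ties broken by the smallest index.
    """
    if path.n_frames < 3:
        raise ValueError("need >= 3 frames")
    V = potential.energy_many(path.coords)
    j = int(np.argmax(V))            # argmax returns the first maximum
    return float(V[j] - V[0]), j


@dataclass
class RunResult:
    seed: int
    path: Path | None
    barrier: float
    barrier_index: int
    mean_potential: float
    report: ConvergenceReport | None
    error: str | None = None


@dataclass
class EnsembleResult:
    runs: list
    selected_index: int

    @property
    def selected(self) -> RunResult:
        return self.runs[self.selected_index]


def _optimize_one(endpoints, potential, params: ActionParams) -> RunResult:
    path = init_trial_path(endpoints, params)
    path, report = minimize_action(path, potential, params)
    best_path, best_report = path, report
    best_barrier, _ = pathway_barrier(path, potential)
    # Lowest-barrier refinement: ratchet the conservation target down to just
    # below the current peak energy.  Once the target falls under the lowest
    # ridge crossing, the penalty squeezes the path through the lowest pass
    # and the peak stops descending; the best (lowest-barrier) path is kept.
    for _ in range(params.anneal_rounds):
        v_max = float(potential.energy_many(path.coords).max())
        e_target = v_max - params.anneal_offset
        path, report = minimize_action(
            path, potential, replace(params, target_energy=e_target))
        barrier, _ = pathway_barrier(path, potential)
        if barrier < best_barrier - 1e-12:
            best_path, best_report, best_barrier = path, report, barrier
        elif barrier > best_barrier + params.anneal_offset:
            break  # target has fallen below the lowest crossing; stop ratcheting
    barrier, j = pathway_barrier(best_path, potential)
    mean_v = float(potential.energy_many(best_path.coords).mean())
    return RunResult(params.seed, best_path, barrier, j, mean_v, best_report)


def run_ensemble(endpoints, potential, params: ActionParams,
                 n_runs: int = 10, seeds=None) -> EnsembleResult:
    """Independent seeded action minimizations + lowest-barrier selection.

    Selection order: smallest barrier, then smallest mean potential energy,
    then seed order.  Individual run failures are recorded; the ensemble
    proceeds as long as one run converges.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = [params.seed + k for k in range(n_runs)]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    runs = []
    for seed in seeds:
        try:
            runs.append(_optimize_one(endpoints, potential,
                                      replace(params, seed=int(seed))))
        except ActionDivergenceError as exc:
            runs.append(RunResult(int(seed), None, np.inf, -1, np.inf,
                                  None, error=str(exc)))
    ok = [k for k, r in enumerate(runs) if r.error is None]
    if not ok:
        raise ActionDivergenceError(
            "all ensemble runs failed: " + "; ".join(r.error for r in runs))
    best = min(ok, key=lambda k: (runs[k].barrier, runs[k].mean_potential, k))
    return EnsembleResult(runs=runs, selected_index=best)
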