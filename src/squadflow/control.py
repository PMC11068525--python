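"""L1-sparse optimal control: which external stimuli steer the network?

Problem: given a fitted SQUAD model, candidate stimulus channels u_k >= 0
(each pushing one node up or down through coupling delta_k) and desired
activities theta_j with importance weights rho_j, minimize

    J(u) = int_0^T sum_j rho_j (x_j(t) - theta_j(t))^2 dt
         + alpha * int_0^T sum_k u_k(t) dt
    s.t.  x' = f(x, u),  x(0) = x0,  0 <= u_k <= u_max.

The second term is an L1 control cost: because u >= 0 on the feasible set
it is linear there, so no nonsmooth machinery is needed — the projection
onto [0, u_max] handles the kink at zero.  Increasing alpha forces
inefficient stimuli to identically zero; the channels that survive a large
alpha are the most effective intervention points (candidate drug targets).

Method: first-discretize-then-optimize single shooting.  Controls are
piecewise constant on a grid; the gradient of the discretized objective is
computed by integrating the adjoint ODE

    lambda' = -(df/dx)^T lambda - 2 rho (x - theta),   lambda(T) = 0

backward segment-by-segment, giving

    dJ/du_{k,i} = int_{seg i} lambda^T df/du_k dt + alpha * dt_i.

A projected-gradient descent with Armijo backtracking then drives the
controls; accepted iterations never increase the objective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import ParameterSet, SquadSystem, StimulusChannel, StimulusProfile
from .errors import ConfigurationError, IntegrationError, ParameterError
from .network import Topology
from .simulation import Trajectory, simulate

DEFAULT_SEGMENTS = 50
DEFAULT_U_MAX = 1.0
ACTIVE_THRESHOLD_FACTOR = 1e-3


# ---------------------------------------------------------------------------
# Desired state
# ---------------------------------------------------------------------------

@dataclass
class Target:
    """Desired value for one node: constant or tabulated over time."""

    theta: float | tuple[np.ndarray, np.ndarray]
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ParameterError(f"target weight rho must be >= 0, got {self.rho}")
        if isinstance(self.theta, (int, float)):
            if not 0.0 <= float(self.theta) <= 1.0:
                raise ParameterError(
                    f"desired value theta must lie in [0, 1], got {self.theta}")
        else:
            times, values = self.theta
            times = np.asarray(times, dtype=float)
            values = np.asarray(values, dtype=float)
            if np.any((values < 0) | (values > 1)):
                raise ParameterError("tabulated theta values must lie in [0, 1]")
            if np.any(np.diff(times) <= 0):
                raise ParameterError("tabulated theta times must increase")
            self.theta = (times, values)

    def at(self, t):
        """Evaluate theta(t); tabulated targets interpolate linearly."""
        if isinstance(self.theta, (int, float)):
            return (np.full_like(np.asarray(t, dtype=float), float(self.theta))
                    if np.ndim(t) else float(self.theta))
        times, values = self.theta
        return np.interp(t, times, values)


@dataclass
class DesiredState:
    """Targets per node; nodes absent here have rho = 0 (no preference)."""

    targets: dict[str, Target]

    def nodes(self) -> list[str]:
        return list(self.targets)

    def rho(self, node: str) -> float:
        tgt = self.targets.get(node)
        return tgt.rho if tgt is not None else 0.0


# ---------------------------------------------------------------------------
# Problem / result containers
# ---------------------------------------------------------------------------

@dataclass
class ControlProblem:
    topology: Topology
    params: ParameterSet                      # fixed, e.g. from a FitResult
    channels: list[StimulusChannel]
    desired: DesiredState
    horizon: float
    alpha: float = 1.0                        # sparsity weight on the L1 cost
    n_segments: int = DEFAULT_SEGMENTS
    u_max: float = DEFAULT_U_MAX
    experiment: str = "default"
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ConfigurationError("horizon T must be positive")
        if self.alpha < 0:
            raise ConfigurationError("sparsity weight alpha must be >= 0")
        if self.n_segments < 1:
            raise ConfigurationError("need at least one control segment")
        for node in self.desired.targets:
            if not self.topology.has_node(node):
                raise ConfigurationError(f"desired state names unknown node {node!r}")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_segments + 1)

    def zero_profile(self) -> StimulusProfile:
        return StimulusProfile([c.id for c in self.channels], self.grid,
                               np.zeros((len(self.channels), self.n_segments)))

    def restricted(self, channel_ids: Sequence[str]) -> "ControlProblem":
        keep = [c for c in self.channels if c.id in set(channel_ids)]
        return replace(self, channels=keep)


@dataclass
class ControlResult:
    profile: StimulusProfile
    tracking: float
    cost: float
    total: float
    tracking_per_node: dict[str, float]
    active_set: list[str]
    trajectory: Trajectory
    converged: bool
    n_iterations: int
    objective_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Standalone objective pieces
# ---------------------------------------------------------------------------

def tracking_objective(trajectory: Trajectory, desired: DesiredState) -> float:
    """Trapezoidal quadrature of sum_j rho_j (x_j - theta_j)^2 on the
    trajectory's own grid."""
    total = 0.0
    for node, tgt in desired.targets.items():
        if tgt.rho == 0.0:
            continue
        x = trajectory.node(node)
        theta = tgt.at(trajectory.times)
        total += tgt.rho * float(np.trapezoid((x - theta) ** 2, trajectory.times))
    return total


def control_cost(profile: StimulusProfile, alpha: float) -> float:
    """alpha times the exact integral of the piecewise-constant sum_k u_k."""
    if np.any(profile.values < 0):
        raise ParameterError("stimulus levels must be non-negative")
    widths = np.diff(profile.grid)
    return float(alpha * np.sum(profile.values @ widths))


# ---------------------------------------------------------------------------
# Solver core
# ---------------------------------------------------------------------------

class _OCPEngine:
    """Shooting + adjoint machinery for one ControlProblem."""

    def __init__(self, problem: ControlProblem):
        self.problem = problem
        self.system = SquadSystem(problem.topology, problem.params,
                                  problem.channels)
        self.grid = problem.grid
        self.widths = np.diff(self.grid)
        self.n_ch = len(problem.channels)
        self.x0 = problem.params.initial_state_vector(
            problem.topology, problem.experiment)
        # targeted nodes: state index, rho, theta evaluator
        self.targets: list[tuple[int, float, Target]] = []
        for node, tgt in problem.desired.targets.items():
            if tgt.rho > 0:
                self.targets.append((self.system.index[node], tgt.rho, tgt))

    # -- forward pass -------------------------------------------------------
    def forward(self, u: np.ndarray):
        """Integrate x plus per-target quadrature states through all segments.

        Returns (dense solutions per segment, tracking per target, x(T)).
        """
        n, m = self.system.n, len(self.targets)
        y = np.concatenate([self.x0, np.zeros(m)])

        def rhs(t, yv, useg):
            x = yv[:n]
            dx = self.system.rhs(t, x, useg)
            dz = np.array([rho * (x[j] - tgt.at(t)) ** 2
                           for j, rho, tgt in self.targets])
            return np.concatenate([dx, dz])

        sols = []
        for i in range(len(self.widths)):
            useg = u[:, i] if self.n_ch else None
            sol = solve_ivp(rhs, (self.grid[i], self.grid[i + 1]), y,
                            args=(useg,), method="LSODA",
                            rtol=self.problem.rtol, atol=self.problem.atol,
                            dense_output=True)
            if not sol.success:
                raise IntegrationError(
                    f"forward integration failed on segment {i}: {sol.message}")
            sols.append(sol)
            y = sol.y[:, -1]
        tracking_parts = y[n:]
        return sols, tracking_parts, y[:n]

    def objective(self, u: np.ndarray):
        _, parts, _ = self.forward(u)
        tracking = float(np.sum(parts))
        cost = float(self.problem.alpha * np.sum(u @ self.widths))
        per_node = {self.system.node_ids[j]: float(p)
                    for (j, _, _), p in zip(self.targets, parts)}
        return tracking + cost, tracking, cost, per_node

    # -- adjoint gradient ---------------------------------------------------
    def gradient(self, u: np.ndarray, sols=None) -> np.ndarray:
        """dJ/du via the adjoint ODE; shape (n_channels, n_segments)."""
        if sols is None:
            sols, _, _ = self.forward(u)
        n, n_ch = self.system.n, self.n_ch
        grad = np.zeros((n_ch, len(self.widths)))
        lam = np.zeros(n)

        def back_rhs(t, yv, sol, useg):
            x = sol.sol(t)[:n]
            lam_ = yv[:n]
            J = self.system.jacobian(t, x, useg)
            gx = np.zeros(n)
            for j, rho, tgt in self.targets:
                gx[j] = 2.0 * rho * (x[j] - tgt.at(t))
            dlam = -J.T @ lam_ - gx
            dG = np.array([lam_ @ self.system.control_jacobian_column(k, x)
                           for k in range(n_ch)])
            return np.concatenate([dlam, dG])

        for i in range(len(self.widths) - 1, -1, -1):
            useg = u[:, i] if n_ch else None
            y0 = np.concatenate([lam, np.zeros(n_ch)])
            sol = solve_ivp(back_rhs, (self.grid[i + 1], self.grid[i]), y0,
                            args=(sols[i], useg), method="LSODA",
                            rtol=self.problem.rtol, atol=self.problem.atol)
            if not sol.success:
                raise IntegrationError(
                    f"adjoint integration failed on segment {i}: {sol.message}")
            yf = sol.y[:, -1]
            lam = yf[:n]
            # integrating backward flips the sign of the accumulated integral
            grad[:, i] = -yf[n:] + self.problem.alpha * self.widths[i]
        return grad

    def finite_difference_gradient(self, u: np.ndarray,
                                   step: float = 1e-4) -> np.ndarray:
        """Central differences of the discretized objective (validation)."""
        grad = np.zeros_like(u)
        for k in range(u.shape[0]):
            for i in range(u.shape[1]):
                up, dn = u.copy(), u.copy()
                up[k, i] += step
                dn[k, i] -= step
                grad[k, i] = (self.objective(up)[0] - self.objective(dn)[0]) / (2 * step)
        return grad


def solve_ocp(problem: ControlProblem,
              init: StimulusProfile | np.ndarray | None = None,
              max_iterations: int = 150, gtol: float = 1e-6,
              ftol: float = 1e-9,
              armijo_c1: float = 1e-4, max_backtracks: int = 40,
              initial_step: float = 1.0) -> ControlResult:
    """Projected-gradient descent on the discretized control problem.

    Starts from the zero profile (the no-intervention baseline) unless an
    ``init`` profile is given.  Feasibility 0 <= u <= u_max holds exactly
    at every iterate (the projection is a clip).  Convergence: projected
    gradient below ``gtol``, or the accepted objective decrease falling
    below ``ftol * max(1, |J|)`` on two consecutive iterations.
    Non-convergence returns the last iterate flagged ``converged=False``
    rather than raising.
    """
    engine = _OCPEngine(problem)
    n_seg = problem.n_segments
    if init is None:
        u = np.zeros((len(problem.channels), n_seg))
    elif isinstance(init, StimulusProfile):
        if init.values.shape != (len(problem.channels), n_seg):
            raise ConfigurationError(
                f"init profile shape {init.values.shape} does not match "
                f"{len(problem.channels)} channels x {n_seg} segments")
        u = init.values.copy()
    else:
        u = np.array(init, dtype=float).reshape(len(problem.channels), n_seg)
    u = np.clip(u, 0.0, problem.u_max)

    total, tracking, cost, per_node = engine.objective(u)
    history = [total]
    converged = False
    step = initial_step
    n_iter = 0
    stall_count = 0

    if len(problem.channels) == 0:
        converged = True
    for n_iter in range(1, max_iterations + 1):
        if not len(problem.channels):
            break
        grad = engine.gradient(u)
        pg = u - np.clip(u - grad, 0.0, problem.u_max)
        if np.max(np.abs(pg)) < gtol:
            converged = True
            break
        accepted = False
        s = step
        for _ in range(max_backtracks):
            u_new = np.clip(u - s * grad, 0.0, problem.u_max)
            d = u - u_new
            decrease = float(np.sum(grad * d))
            if decrease <= 0.0:
                break  # projection removed every descent component
            new_total, new_tracking, new_cost, new_per_node = engine.objective(u_new)
            if new_total <= total - armijo_c1 * decrease + 1e-10:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            # no further progress possible at line-search resolution
            converged = bool(np.max(np.abs(pg)) < 1e2 * gtol)
            break
        decrease_achieved = total - new_total
        u, total = u_new, new_total
        tracking, cost, per_node = new_tracking, new_cost, new_per_node
        history.append(total)
        step = min(s * 2.0, 1e3)
        if decrease_achieved < ftol * max(1.0, abs(total)):
            stall_count += 1
            if stall_count >= 2:
                converged = True
                break
        else:
            stall_count = 0

    profile = StimulusProfile([c.id for c in problem.channels],
                              problem.grid.copy(), u)
    threshold = ACTIVE_THRESHOLD_FACTOR * max(1.0, problem.u_max)
    active = [c.id for k, c in enumerate(problem.channels)
              if u.shape[1] and float(np.max(u[k])) > threshold]
    t_fine = np.linspace(0.0, problem.horizon, max(200, 4 * n_seg) + 1)
    traj = simulate(problem.topology, problem.params, profile=profile,
                    t_eval=t_fine, channels=tuple(problem.channels),
                    experiment=problem.experiment,
                    rtol=problem.rtol, atol=problem.atol)
    return ControlResult(profile, tracking, cost, tracking + cost, per_node,
                         active, traj, converged, n_iter, history)


def baseline_trajectory(problem: ControlProblem
                        ) -> tuple[Trajectory, float, dict[str, float]]:
    """No-intervention reference: all stimuli identically zero.

    Returns the trajectory, the tracking term and its per-node breakdown,
    computed with the same quadrature the solver uses so comparisons are
    like-for-like.
    """
    engine = _OCPEngine(problem)
    u = np.zeros((len(problem.channels), problem.n_segments))
    _, tracking, _, per_node = engine.objective(u)
    t_fine = np.linspace(0.0, problem.horizon, max(200, 4 * problem.n_segments) + 1)
    traj = simulate(problem.topology, problem.params, profile=None,
                    t_eval=t_fine, channels=tuple(problem.channels),
                    experiment=problem.experiment,
                    rtol=problem.rtol, atol=problem.atol)
    return traj, tracking, per_node


def alpha_sweep(problem: ControlProblem, alphas: Sequence[float],
                activity_threshold: float | None = None,
                **solve_kw) -> tuple[list[ControlResult], pd.DataFrame]:
    """Solve for increasing alpha, warm-starting each solve from the last.

    As alpha grows, stimuli whose steering benefit no longer outweighs
    their cost drop to zero; the surviving active set names the most
    effective intervention points.  Returns per-alpha results and a tidy
    table (alpha, channel, max level, active flag, objective pieces).
    """
    alphas = list(alphas)
    if not alphas:
        raise ConfigurationError("alpha sweep needs at least one alpha")
    if any(b < a for a, b in zip(alphas, alphas[1:])):
        raise ConfigurationError("alphas must be non-decreasing")
    threshold = (activity_threshold if activity_threshold is not None
                 else ACTIVE_THRESHOLD_FACTOR * max(1.0, problem.u_max))
    results: list[ControlResult] = []
    rows = []
    init: StimulusProfile | None = None
    for a in alphas:
        sub = replace(problem, alpha=float(a))
        res = solve_ocp(sub, init=init, **solve_kw)
        results.append(res)
        init = res.profile
        for k, ch in enumerate(problem.channels):
            umax_k = float(np.max(res.profile.values[k])) if problem.channels else 0.0
            rows.append((a, ch.id, umax_k, umax_k > threshold,
                         res.tracking, res.cost, res.total))
    table = pd.DataFrame(rows, columns=["alpha", "channel", "max_u", "active",
                                        "tracking", "cost", "total"])
    return results, table


def scenario_report(problem: ControlProblem,
                    channel_subsets: Sequence[Sequence[str]],
                    **solve_kw) -> tuple[pd.DataFrame, list[ControlResult]]:
    """Solve the same problem restricted to each candidate channel subset.

    All solves share the problem's alpha so objective differences reflect
    the stimuli themselves, enabling synergy comparisons (combined set vs
    singletons).  Each solve is warm-started from the best already-solved
    sub-subset solution (embedded with zeros for the extra channels), so a
    superset can never end up worse than a subset it contains.
    """
    all_ids = [c.id for c in problem.channels]
    for subset in channel_subsets:
        unknown = set(subset) - set(all_ids)
        if unknown:
            raise ConfigurationError(f"unknown channels in subset: {sorted(unknown)}")
    solved: list[tuple[set[str], ControlResult]] = []
    results: list[ControlResult] = []
    rows = []
    for subset in channel_subsets:
        sub_ids = [cid for cid in all_ids if cid in set(subset)]
        sub = problem.restricted(sub_ids)
        # candidate starts: cold zero plus embeddings of solved sub-subsets
        candidates: list[np.ndarray] = [np.zeros((len(sub_ids), problem.n_segments))]
        for prev_ids, prev_res in solved:
            if prev_ids <= set(sub_ids):
                emb = np.zeros((len(sub_ids), problem.n_segments))
                for k, cid in enumerate(sub_ids):
                    if cid in prev_ids:
                        row = prev_res.profile.channel_ids.index(cid)
                        emb[k] = prev_res.profile.values[row]
                candidates.append(emb)
        engine = _OCPEngine(sub)
        objs = [engine.objective(c)[0] for c in candidates]
        best_init = candidates[int(np.argmin(objs))]
        res = solve_ocp(sub, init=best_init, **solve_kw)
        solved.append((set(sub_ids), res))
        results.append(res)
        rows.append((",".join(sub_ids) if sub_ids else "(none)",
                     res.tracking, res.cost, res.total,
                     ",".join(res.active_set)))
    table = pd.DataFrame(rows, columns=["subset", "tracking", "cost",
                                        "total", "active_set"])
    return table, results


def grid_search_constant(problem: ControlProblem,
                         levels: Sequence[float]) -> tuple[np.ndarray, float]:
    """Exhaustive search over constant control levels (validation helper).

    Evaluates the same discretized objective on every combination of the
    given levels across channels; exponential in the channel count, so only
    sensible for one or two channels.
    """
    engine = _OCPEngine(problem)
    n_ch = len(problem.channels)
    best_levels, best_obj = None, np.inf
    for combo in itertools.product(levels, repeat=n_ch):
        u = np.tile(np.asarray(combo, dtype=float)[:, None],
                    (1, problem.n_segments))
        obj = engine.objective(u)[0]
        if obj < best_obj:
            best_obj, best_levels = obj, np.asarray(combo, dtype=float)
    return best_levels, float(best_obj)


def adjoint_gradient(problem: ControlProblem,
                     u: np.ndarray) -> np.ndarray:
    """Public adjoint gradient of the discretized objective at ``u``."""
    return _OCPEngine(problem).gradient(np.asarray(u, dtype=float))


def finite_difference_gradient(problem: ControlProblem, u: np.ndarray,
                               step: float = 1e-4) -> np.ndarray:
    """Central-difference gradient (slow; for verification only)."""
    return _OCPEngine(problem).finite_difference_gradient(
        np.asarray(u, dtype=float), step)
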