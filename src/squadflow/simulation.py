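"""Time integration of SQUAD systems.

Integration is segment-wise: the solver is restarted at every breakpoint of
the (piecewise-constant) stimulus profile so control discontinuities never
degrade the integrator's order.  The default solver is LSODA (switches to a
stiff BDF method automatically — fitted steepness values can make the
system stiff) at rtol 1e-8 / atol 1e-10.

States are never clipped: boundedness in [0, 1] is a property of the model
and is asserted, not enforced, so that modeling errors surface in tests.
A breach beyond tolerance attaches a warning to the trajectory instead of
silently sanitizing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import ParameterSet, SquadSystem, StimulusChannel, StimulusProfile
from .errors import IntegrationError, ParameterError
from .network import Topology

BOUND_TOL = 1e-6


@dataclass
class Trajectory:
    """Solution of the initial-value problem on a reporting grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_nodes)
    node_ids: list[str]
    profile: StimulusProfile | None = None
    warnings: list[str] = field(default_factory=list)

    def node(self, node_id: str) -> np.ndarray:
        return self.states[:, self.node_ids.index(node_id)]

    def at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ParameterError(f"time {t} not on the trajectory grid")
        return self.states[i]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: time, node, value."""
        rows = []
        for i, t in enumerate(self.times):
            for j, nid in enumerate(self.node_ids):
                rows.append((t, nid, self.states[i, j]))
        return pd.DataFrame(rows, columns=["time", "node", "value"])


def _segment_times(t_eval: np.ndarray,
                   profile: StimulusProfile | None) -> list[tuple[float, float]]:
    """Integration segments: [0, T] cut at interior profile breakpoints."""
    t_end = float(t_eval[-1])
    cuts = [0.0]
    if profile is not None:
        cuts.extend(float(b) for b in profile.grid if 0.0 < b < t_end)
    cuts.append(t_end)
    cuts = sorted(set(cuts))
    return list(zip(cuts[:-1], cuts[1:]))


def simulate(topology: Topology, params: ParameterSet,
             profile: StimulusProfile | None = None,
             t_eval: np.ndarray | None = None,
             channels: tuple[StimulusChannel, ...] = (),
             experiment: str = "default",
             x0: np.ndarray | None = None,
             method: str = "LSODA", rtol: float = 1e-8, atol: float = 1e-10,
             system: SquadSystem | None = None) -> Trajectory:
    """Integrate the SQUAD ODE and report states at ``t_eval``.

    ``t_eval`` must be increasing and start at 0.  The initial state comes
    from ``params.initial_states[experiment]`` unless ``x0`` is given
    explicitly.  Passing a prebuilt ``system`` skips recompilation (used in
    fitting inner loops).
    """
    if t_eval is None:
        t_eval = np.linspace(0.0, profile.horizon if profile else 10.0, 101)
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or len(t_eval) < 1:
        raise ParameterError("t_eval must be a non-empty 1-D time vector")
    if np.any(np.diff(t_eval) <= 0):
        raise ParameterError("t_eval must be strictly increasing")
    if abs(t_eval[0]) > 1e-12:
        raise ParameterError("t_eval must start at time 0")

    if system is None:
        system = SquadSystem(topology, params, channels)
    if x0 is None:
        x0 = params.initial_state_vector(topology, experiment)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (system.n,):
        raise ParameterError(f"x0 has shape {x0.shape}, expected ({system.n},)")

    if len(t_eval) == 1:  # only t=0 requested
        return Trajectory(t_eval.copy(), x0[None, :].copy(), system.node_ids, profile)

    out = np.empty((len(t_eval), system.n))
    out[0] = x0
    state = x0.copy()
    filled = 1
    for t_lo, t_hi in _segment_times(t_eval, profile):
        u = profile.levels_at(t_lo) if profile is not None else None
        mask = (t_eval > t_lo + 1e-15) & (t_eval <= t_hi + 1e-15)
        seg_eval = t_eval[mask]
        sol = solve_ivp(
            lambda t, x: system.rhs(t, x, u),
            (t_lo, t_hi), state, method=method,
            t_eval=seg_eval if len(seg_eval) else None,
            rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t_lo}, {t_hi}]: {sol.message}")
        if len(seg_eval):
            out[filled:filled + len(seg_eval)] = sol.y.T
            filled += len(seg_eval)
        state = sol.y[:, -1] if sol.y.shape[1] else state

    traj = Trajectory(t_eval.copy(), out, system.node_ids, profile)
    lo, hi = out.min(), out.max()
    if lo < -BOUND_TOL or hi > 1.0 + BOUND_TOL:
        traj.warnings.append(
            f"trajectory left [0,1] beyond tolerance: min={lo:.3g}, max={hi:.3g}")
    return traj


def relax_to_equilibrium(topology: Topology, params: ParameterSet,
                         profile: StimulusProfile | None = None,
                         channels: tuple[StimulusChannel, ...] = (),
                         experiment: str = "default",
                         x0: np.ndarray | None = None,
                         max_time: float = 200.0, tol: float = 1e-8,
                         chunk: float = 10.0,
                         **solver_kw) -> tuple[np.ndarray, bool]:
    """Integrate until the right-hand side is below ``tol`` in max-norm.

    Returns (final state, converged flag).  With a constant (or absent)
    stimulus this finds the equilibrium the network relaxes into from the
    given initial state — e.g. the ground state before any intervention.
    """
    if tol <= 0:
        raise ParameterError("tol must be positive")
    system = SquadSystem(topology, params, channels)
    if x0 is None:
        x0 = params.initial_state_vector(topology, experiment)
    state = np.asarray(x0, dtype=float).copy()
    u = profile.levels_at(0.0) if profile is not None else None
    elapsed = 0.0
    while elapsed < max_time:
        if np.max(np.abs(system.rhs(elapsed, state, u))) < tol:
            return state, True
        step = min(chunk, max_time - elapsed)
        traj = simulate(topology, params, profile=None,
                        t_eval=np.array([0.0, step]), channels=channels,
                        x0=state, system=system, **solver_kw)
        if profile is not None:
            # constant stimulus: re-simulate manually with fixed u
            sol = solve_ivp(lambda t, x: system.rhs(t, x, u), (0.0, step),
                            state, method="LSODA", rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise IntegrationError(f"relaxation failed: {sol.message}")
            state = sol.y[:, -1]
        else:
            state = traj.states[-1]
        elapsed += step
    converged = bool(np.max(np.abs(system.rhs(elapsed, state, u))) < tol)
    return state, converged
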