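"""SQUAD continuous-logic dynamics.

Each non-constant node j carries an activity level x_j in [0, 1] obeying

    dx_j/dt = A(w_j, h_j) - gamma_j * x_j + r_j

where ``A`` is a normalized sigmoid of the combined regulatory input w_j,
h_j tunes its steepness, gamma_j is a first-order decay (fixed to 1 by
default so that levels stay inside [0, 1]) and r_j collects external
stimulus terms.  The combined input w_j aggregates weighted activator and
inhibitor activities into [0, 1]:

    act  = ((1 + S_a) / S_a) * (A_x / (1 + A_x)),  S_a = sum(alpha),
                                                   A_x = sum(alpha * x_act)
    inh  = ((1 + S_b) / S_b) * (B_x / (1 + B_x)),  analogous with beta
    w    = act * (1 - inh)    if both regulator classes present
         = act                if only activators
         = 1 - inh            if only inhibitors

An external stimulus channel k with non-negative time course u_k(t) and
coupling delta_k contributes

    r_j += delta_k * u_k * (1 - x_j)   (up-regulating)
    r_j += -delta_k * u_k * x_j        (down-regulating)

so that stimulation can never push a level outside [0, 1]: an up-stimulus
has no effect on a fully expressed gene, a down-stimulus none on a silent
one.  Unregulated nodes have activation term 0 (they decay unless
stimulated); constant nodes have derivative 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateWeightsError, LookupError_, ParameterError
from .network import ACTIVATING, INHIBITING, Topology

Direction = Literal["up", "down"]


# ---------------------------------------------------------------------------
# Elementary terms
# ---------------------------------------------------------------------------

def activation_response(w, h: float):
    """Normalized sigmoid activation term.

    A(w, h) = (-exp(h/2) + exp(-h(w - 1/2))) /
              ((1 - exp(h/2)) * (1 + exp(-h(w - 1/2))))

    Maps [0, 1] -> [0, 1] with A(0)=0, A(1/2)=1/2, A(1)=1 for every h > 0,
    strictly increasing in w.  Vectorized over ``w``.
    """
    if h <= 0:
        raise ParameterError(f"steepness h must be positive, got {h}")
    w = np.asarray(w, dtype=float)
    e_half = np.exp(0.5 * h)
    z = np.exp(-h * (w - 0.5))
    out = (-e_half + z) / ((1.0 - e_half) * (1.0 + z))
    return out if out.ndim else float(out)


def activation_response_dw(w, h: float):
    """Derivative of :func:`activation_response` with respect to w."""
    if h <= 0:
        raise ParameterError(f"steepness h must be positive, got {h}")
    w = np.asarray(w, dtype=float)
    e_half = np.exp(0.5 * h)
    z = np.exp(-h * (w - 0.5))
    out = -h * z * (1.0 + e_half) / ((1.0 - e_half) * (1.0 + z) ** 2)
    return out if out.ndim else float(out)


def _saturating_part(levels: np.ndarray, weights: np.ndarray, what: str) -> float:
    s = float(np.sum(weights))
    if s <= 0.0:
        raise DegenerateWeightsError(
            f"{what} present but their weights sum to {s}; the prefactor "
            f"(1+sum)/sum is undefined")
    sx = float(np.dot(weights, levels))
    return ((1.0 + s) / s) * (sx / (1.0 + sx))


def combined_input(activator_levels: Sequence[float],
                   activator_weights: Sequence[float],
                   inhibitor_levels: Sequence[float] = (),
                   inhibitor_weights: Sequence[float] = ()) -> float:
    """Combined regulatory input w in [0, 1].

    At least one regulator class must be non-empty; the unregulated case is
    resolved in :func:`squad_rhs` (activation term 0).
    """
    a_lvl = np.asarray(activator_levels, dtype=float)
    a_w = np.asarray(activator_weights, dtype=float)
    i_lvl = np.asarray(inhibitor_levels, dtype=float)
    i_w = np.asarray(inhibitor_weights, dtype=float)
    if a_lvl.size == 0 and i_lvl.size == 0:
        raise ParameterError("combined_input requires at least one regulator")
    if a_lvl.size:
        act = _saturating_part(a_lvl, a_w, "activators")
    if i_lvl.size:
        inh = _saturating_part(i_lvl, i_w, "inhibitors")
    if a_lvl.size and i_lvl.size:
        w = act * (1.0 - inh)
    elif a_lvl.size:
        w = act
    else:
        w = 1.0 - inh
    # mathematically in [0,1] for levels in [0,1]; guard rounding only
    return float(min(max(w, 0.0), 1.0))


def stimulus_term(direction: Direction, delta: float, u: float, x: float) -> float:
    """External-stimulus contribution r for one channel on one node."""
    if delta < 0 or u < 0:
        raise ParameterError("stimulus coupling delta and level u must be >= 0")
    if direction == "up":
        return delta * u * (1.0 - x)
    if direction == "down":
        return -delta * u * x
    raise ParameterError(f"unknown stimulus direction {direction!r}")


# ---------------------------------------------------------------------------
# Parameters, channels, profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusChannel:
    """One controllable external input acting on a single node."""

    id: str
    target: str
    direction: Direction

    @property
    def coupling_id(self) -> str:
        return f"d_{self.id}"


@dataclass
class StimulusProfile:
    """Piecewise-constant stimulus time courses on a shared grid.

    ``grid`` holds the n_seg+1 breakpoints covering [0, T]; ``values`` is
    (n_channels, n_seg).  The value on [t_i, t_{i+1}) is values[:, i]
    (right-open convention); t >= T evaluates to the last segment.
    """

    channel_ids: list[str]
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.grid.ndim != 1 or len(self.grid) < 2:
            raise ParameterError("profile grid needs at least two breakpoints")
        if np.any(np.diff(self.grid) <= 0):
            raise ParameterError("profile grid must be strictly increasing")
        if self.values.shape != (len(self.channel_ids), len(self.grid) - 1):
            raise ParameterError(
                f"profile values shape {self.values.shape} does not match "
                f"{len(self.channel_ids)} channels x {len(self.grid) - 1} segments")
        if np.any(self.values < 0):
            raise ParameterError("stimulus levels must be non-negative")

    @classmethod
    def zero(cls, channel_ids: Sequence[str], horizon: float,
             n_segments: int = 1) -> "StimulusProfile":
        grid = np.linspace(0.0, horizon, n_segments + 1)
        return cls(list(channel_ids), grid, np.zeros((len(channel_ids), n_segments)))

    @classmethod
    def constant(cls, channel_ids: Sequence[str], levels: Sequence[float],
                 horizon: float, n_segments: int = 1) -> "StimulusProfile":
        grid = np.linspace(0.0, horizon, n_segments + 1)
        vals = np.tile(np.asarray(levels, dtype=float)[:, None], (1, n_segments))
        return cls(list(channel_ids), grid, vals)

    @property
    def horizon(self) -> float:
        return float(self.grid[-1])

    def segment_index(self, t: float) -> int:
        i = int(np.searchsorted(self.grid, t, side="right")) - 1
        return min(max(i, 0), self.values.shape[1] - 1)

    def levels_at(self, t: float) -> np.ndarray:
        return self.values[:, self.segment_index(t)]

    def level_at(self, channel_id: str, t: float) -> float:
        k = self.channel_ids.index(channel_id)
        return float(self.values[k, self.segment_index(t)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, cid in enumerate(self.channel_ids):
            for i in range(self.values.shape[1]):
                rows.append((self.grid[i], cid, self.values[k, i]))
        return pd.DataFrame(rows, columns=["time", "channel", "value"])


@dataclass
class ParameterSet:
    """All SQUAD parameters for one topology.

    Edge weights are keyed by (source, target); steepness/decay by node id;
    stimulus couplings by channel id; initial states by experiment label
    then node id.
    """

    activator_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    inhibitor_weights: dict[tuple[str, str], float] = field(default_factory=dict)
    steepness: dict[str, float] = field(default_factory=dict)
    decay: dict[str, float] = field(default_factory=dict)
    couplings: dict[str, float] = field(default_factory=dict)
    initial_states: dict[str, dict[str, float]] = field(default_factory=dict)

    # -- flat-id view (used by the optimizer and the parameter table) -------
    @staticmethod
    def weight_id(sign: str, source: str, target: str) -> str:
        prefix = "a" if sign == ACTIVATING else "b"
        return f"{prefix}_{source}__{target}"

    def to_flat(self) -> dict[str, float]:
        flat: dict[str, float] = {}
        for (s, t), v in self.activator_weights.items():
            flat[f"a_{s}__{t}"] = v
        for (s, t), v in self.inhibitor_weights.items():
            flat[f"b_{s}__{t}"] = v
        for n, v in self.steepness.items():
            flat[f"h_{n}"] = v
        for n, v in self.decay.items():
            flat[f"g_{n}"] = v
        for c, v in self.couplings.items():
            flat[f"d_{c}"] = v
        for exp, states in self.initial_states.items():
            for n, v in states.items():
                flat[f"x0_{exp}__{n}"] = v
        return flat

    def set_flat(self, pid: str, value: float) -> None:
        kind, _, rest = pid.partition("_")
        if kind in ("a", "b"):
            s, _, t = rest.partition("__")
            target = self.activator_weights if kind == "a" else self.inhibitor_weights
            target[(s, t)] = value
        elif kind == "h":
            self.steepness[rest] = value
        elif kind == "g":
            self.decay[rest] = value
        elif kind == "d":
            self.couplings[rest] = value
        elif kind == "x0":
            exp, _, n = rest.partition("__")
            self.initial_states.setdefault(exp, {})[n] = value
        else:
            raise LookupError_(f"unrecognized parameter id {pid!r}")

    def get_flat(self, pid: str) -> float:
        flat = self.to_flat()
        try:
            return flat[pid]
        except KeyError:
            raise LookupError_(f"unknown parameter id {pid!r}") from None

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            dict(self.activator_weights), dict(self.inhibitor_weights),
            dict(self.steepness), dict(self.decay), dict(self.couplings),
            {k: dict(v) for k, v in self.initial_states.items()})

    def validate_for(self, topology: Topology,
                     channels: Sequence[StimulusChannel] = ()) -> None:
        """Raise if any parameter a simulation needs is missing or invalid."""
        missing: list[str] = []
        for e in topology.edges:
            table = (self.activator_weights if e.sign == ACTIVATING
                     else self.inhibitor_weights)
            if (e.source, e.target) not in table:
                missing.append(self.weight_id(e.sign, e.source, e.target))
        for n in topology.non_constant_nodes():
            if n.id not in self.steepness:
                missing.append(f"h_{n.id}")
            if n.id not in self.decay:
                missing.append(f"g_{n.id}")
        for ch in channels:
            if ch.id not in self.couplings:
                missing.append(f"d_{ch.id}")
        if missing:
            raise ParameterError("missing parameters: " + ", ".join(sorted(missing)))
        for key, v in self.activator_weights.items():
            if v < 0:
                raise ParameterError(f"activator weight {key} negative: {v}")
        for key, v in self.inhibitor_weights.items():
            if v < 0:
                raise ParameterError(f"inhibitor weight {key} negative: {v}")
        for n, v in self.steepness.items():
            if v <= 0:
                raise ParameterError(f"steepness h_{n} must be positive: {v}")
        for n, v in self.decay.items():
            if v <= 0:
                raise ParameterError(f"decay g_{n} must be positive: {v}")
        for c, v in self.couplings.items():
            if v < 0:
                raise ParameterError(f"coupling d_{c} negative: {v}")

    def initial_state_vector(self, topology: Topology,
                             experiment: str = "default") -> np.ndarray:
        states = self.initial_states.get(experiment)
        if states is None:
            raise ParameterError(
                f"no initial states stored for experiment {experiment!r}")
        try:
            return np.array([states[n.id] for n in topology.nodes], dtype=float)
        except KeyError as exc:
            raise ParameterError(
                f"initial state missing for node {exc.args[0]!r} "
                f"in experiment {experiment!r}") from None


def default_parameters(topology: Topology,
                       channels: Sequence[StimulusChannel] = (),
                       experiments: Sequence[str] = ("default",),
                       weight: float = 1.0, steepness: float = 10.0,
                       decay: float = 1.0, coupling: float = 1.0,
                       x0: float = 0.5) -> ParameterSet:
    """Complete parameter set with uniform default values."""
    p = ParameterSet()
    for e in topology.edges:
        table = p.activator_weights if e.sign == ACTIVATING else p.inhibitor_weights
        table[(e.source, e.target)] = weight
    for n in topology.non_constant_nodes():
        p.steepness[n.id] = steepness
        p.decay[n.id] = decay
    for n in topology.nodes:
        if n.kind == "constant":
            p.decay[n.id] = decay  # unused dynamically; kept for completeness
    for ch in channels:
        p.couplings[ch.id] = coupling
    for exp in experiments:
        p.initial_states[exp] = {n.id: x0 for n in topology.nodes}
    return p


# ---------------------------------------------------------------------------
# Compiled system
# ---------------------------------------------------------------------------

class SquadSystem:
    """Topology + parameters compiled to index arrays for fast evaluation.

    Provides the right-hand side and its analytic state Jacobian; both are
    pure functions of (t, x, u).
    """

    def __init__(self, topology: Topology, params: ParameterSet,
                 channels: Sequence[StimulusChannel] = ()):
        params.validate_for(topology, channels)
        self.topology = topology
        self.params = params
        self.channels = list(channels)
        self.node_ids = topology.node_ids
        self.index = {nid: i for i, nid in enumerate(self.node_ids)}
        self.n = len(self.node_ids)

        self._constant = np.array(
            [n.kind == "constant" for n in topology.nodes], dtype=bool)
        self._h = np.array(
            [params.steepness.get(n.id, 1.0) for n in topology.nodes])
        self._gamma = np.array(
            [params.decay.get(n.id, 1.0) for n in topology.nodes])

        self._act_idx: list[np.ndarray] = []
        self._act_w: list[np.ndarray] = []
        self._inh_idx: list[np.ndarray] = []
        self._inh_w: list[np.ndarray] = []
        for n in topology.nodes:
            acts, inhs = topology.regulators_of(n.id)
            self._act_idx.append(np.array([self.index[a] for a in acts], dtype=int))
            self._act_w.append(np.array(
                [params.activator_weights[(a, n.id)] for a in acts]))
            self._inh_idx.append(np.array([self.index[i] for i in inhs], dtype=int))
            self._inh_w.append(np.array(
                [params.inhibitor_weights[(i, n.id)] for i in inhs]))

        # stimulus bookkeeping: channel k -> (node index, +/-1, delta)
        self._stim: list[tuple[int, float, float]] = []
        for ch in self.channels:
            j = self.index[ch.target]
            if self._constant[j]:
                raise ParameterError(
                    f"stimulus channel {ch.id!r} targets constant node {ch.target!r}")
            sgn = 1.0 if ch.direction == "up" else -1.0
            self._stim.append((j, sgn, params.couplings[ch.id]))

    # -- evaluation ---------------------------------------------------------
    def combined_inputs(self, x: np.ndarray) -> np.ndarray:
        w = np.zeros(self.n)
        for j in range(self.n):
            if self._constant[j]:
                continue
            na, ni = len(self._act_idx[j]), len(self._inh_idx[j])
            if na == 0 and ni == 0:
                continue
            if na:
                sa = self._act_w[j].sum()
                ax = float(self._act_w[j] @ x[self._act_idx[j]])
                act = ((1.0 + sa) / sa) * (ax / (1.0 + ax))
            if ni:
                sb = self._inh_w[j].sum()
                bx = float(self._inh_w[j] @ x[self._inh_idx[j]])
                inh = ((1.0 + sb) / sb) * (bx / (1.0 + bx))
            if na and ni:
                w[j] = act * (1.0 - inh)
            elif na:
                w[j] = act
            else:
                w[j] = 1.0 - inh
        return w

    def rhs(self, t: float, x: np.ndarray,
            u: np.ndarray | None = None) -> np.ndarray:
        """dx/dt at state x under stimulus levels u (one entry per channel)."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ParameterError(
                f"state has shape {x.shape}, expected ({self.n},)")
        dx = np.zeros(self.n)
        w = self.combined_inputs(x)
        for j in range(self.n):
            if self._constant[j]:
                continue
            regulated = len(self._act_idx[j]) or len(self._inh_idx[j])
            act = activation_response(w[j], self._h[j]) if regulated else 0.0
            dx[j] = act - self._gamma[j] * x[j]
        if u is not None and len(self._stim):
            u = np.asarray(u, dtype=float)
            for k, (j, sgn, delta) in enumerate(self._stim):
                if sgn > 0:
                    dx[j] += delta * u[k] * (1.0 - x[j])
                else:
                    dx[j] -= delta * u[k] * x[j]
        return dx

    def jacobian(self, t: float, x: np.ndarray,
                 u: np.ndarray | None = None) -> np.ndarray:
        """Analytic d(rhs)/dx, used by the adjoint integrator."""
        x = np.asarray(x, dtype=float)
        J = np.zeros((self.n, self.n))
        w = self.combined_inputs(x)
        for j in range(self.n):
            if self._constant[j]:
                continue
            J[j, j] -= self._gamma[j]
            na, ni = len(self._act_idx[j]), len(self._inh_idx[j])
            if na == 0 and ni == 0:
                continue
            dA = activation_response_dw(w[j], self._h[j])
            # dw/dx via the saturating parts
            if na:
                sa = self._act_w[j].sum()
                ax = float(self._act_w[j] @ x[self._act_idx[j]])
                act = ((1.0 + sa) / sa) * (ax / (1.0 + ax))
                dact = ((1.0 + sa) / sa) * self._act_w[j] / (1.0 + ax) ** 2
            if ni:
                sb = self._inh_w[j].sum()
                bx = float(self._inh_w[j] @ x[self._inh_idx[j]])
                inh = ((1.0 + sb) / sb) * (bx / (1.0 + bx))
                dinh = ((1.0 + sb) / sb) * self._inh_w[j] / (1.0 + bx) ** 2
            if na and ni:
                for a_pos, i_src in enumerate(self._act_idx[j]):
                    J[j, i_src] += dA * dact[a_pos] * (1.0 - inh)
                for i_pos, i_src in enumerate(self._inh_idx[j]):
                    J[j, i_src] += dA * (-act * dinh[i_pos])
            elif na:
                for a_pos, i_src in enumerate(self._act_idx[j]):
                    J[j, i_src] += dA * dact[a_pos]
            else:
                for i_pos, i_src in enumerate(self._inh_idx[j]):
                    J[j, i_src] += dA * (-dinh[i_pos])
        if u is not None and len(self._stim):
            u = np.asarray(u, dtype=float)
            for k, (j, sgn, delta) in enumerate(self._stim):
                # both directions contribute -delta*u to d(rhs_j)/dx_j
                J[j, j] -= delta * u[k]
        return J

    def control_jacobian_column(self, k: int, x: np.ndarray) -> np.ndarray:
        """d(rhs)/du_k — a vector with a single non-zero entry."""
        j, sgn, delta = self._stim[k]
        col = np.zeros(self.n)
        col[j] = delta * (1.0 - x[j]) if sgn > 0 else -delta * x[j]
        return col


def squad_rhs(t: float, state: np.ndarray, topology: Topology,
              params: ParameterSet,
              channels: Sequence[StimulusChannel] = (),
              profile: StimulusProfile | None = None) -> np.ndarray:
    """Convenience one-shot evaluation of the SQUAD right-hand side.

    For repeated evaluation (simulation, fitting) build a
    :class:`SquadSystem` once instead.
    """
    system = SquadSystem(topology, params, channels)
    u = profile.levels_at(t) if profile is not None else None
    return system.rhs(t, np.asarray(state, dtype=float), u)


# ---------------------------------------------------------------------------
# Parameter table I/O (tabular format: parameterId ... estimate)
# ---------------------------------------------------------------------------

PARAMETER_TABLE_COLUMNS = ["parameterId", "parameterScale", "lowerBound",
                           "upperBound", "nominalValue", "estimate"]


def write_parameter_table(params: ParameterSet, path,
                          bounds: dict[str, tuple[float, float]] | None = None,
                          free: Sequence[str] | None = None) -> pd.DataFrame:
    """Write all parameters as a TSV table.

    ``bounds`` and ``free`` default to wide bounds and nothing estimated;
    the fitting module passes its box and free-parameter spec through.
    """
    bounds = bounds or {}
    free_set = set(free or ())
    rows = []
    for pid, value in sorted(params.to_flat().items()):
        lo, hi = bounds.get(pid, (0.0, 100.0))
        rows.append((pid, "lin", lo, hi, value, int(pid in free_set)))
    df = pd.DataFrame(rows, columns=PARAMETER_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_parameter_table(path) -> tuple[ParameterSet, dict[str, tuple[float, float]],
                                        list[str]]:
    """Read a parameter TSV back into (params, bounds, free ids)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARAMETER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"parameter table missing columns {missing}")
    params = ParameterSet()
    bounds: dict[str, tuple[float, float]] = {}
    free: list[str] = []
    for r in df.itertuples():
        params.set_flat(r.parameterId, float(r.nominalValue))
        bounds[r.parameterId] = (float(r.lowerBound), float(r.upperBound))
        if int(r.estimate):
            free.append(r.parameterId)
    return params, bounds, free
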