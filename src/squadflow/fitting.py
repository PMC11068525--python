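"""Best-parameter fitting: bounded nonlinear least squares on the
chi-square objective

    chi2(p) = sum_l sum_i sum_j ((x_{l,j}(t_i; p) - x~_{l,j,i}) / sigma_{l,j,i})^2

over experiments l, measurement times i and observed genes j.  Model values
come from simulating the SQUAD system under each experiment's stimulus
schedule and initial state.  Free parameters (edge weights, steepnesses,
stimulus couplings, per-experiment initial states; decays stay fixed at 1
by default) are box-constrained; optimization uses trust-region-reflective
least squares on the residual vector, with multi-start via seeded Latin
hypercube sampling of the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .dataprep import MeasurementSeries
from .dynamics import (ParameterSet, SquadSystem, StimulusChannel,
                       StimulusProfile, read_parameter_table)
from .errors import ConfigurationError, DataError, ParameterError, WarmStartError
from .network import ACTIVATING, INHIBITING, Topology
from .simulation import simulate

# Default parameter box D. The weights' lower bound keeps the combined-input
# prefactor (1+S)/S finite; h >= 1 keeps the sigmoid responsive. All
# user-overridable per parameter.
DEFAULT_BOUNDS = {
    "a": (1e-3, 50.0),   # activating edge weights
    "b": (1e-3, 50.0),   # inhibiting edge weights
    "h": (1.0, 50.0),    # steepness
    "d": (0.0, 50.0),    # stimulus couplings
    "x0": (0.0, 1.0),    # initial states
    "g": (1e-2, 10.0),   # decay (fixed by default; bounds used if freed)
}

DEFAULT_INIT = {"a": 1.0, "b": 1.0, "h": 10.0, "d": 1.0, "g": 1.0}


def _id_kind(pid: str) -> str:
    return pid.split("_", 1)[0] if not pid.startswith("x0_") else "x0"


@dataclass
class Experiment:
    """One measured condition: per-gene series plus the applied stimuli."""

    label: str
    series: dict[str, MeasurementSeries]
    profile: StimulusProfile | None = None
    use_sem: bool = False

    def measurement_times(self) -> np.ndarray:
        times = sorted({float(t) for s in self.series.values() for t in s.times})
        return np.asarray(times, dtype=float)


@dataclass
class FitProblem:
    """Everything the optimizer needs: model, data, free spec, box."""

    topology: Topology
    experiments: list[Experiment]
    channels: list[StimulusChannel] = field(default_factory=list)
    baseline: ParameterSet | None = None      # values for all parameters
    free_parameters: list[str] = field(default_factory=list)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        for exp in self.experiments:
            for g in exp.series:
                if not self.topology.has_node(g):
                    raise DataError(
                        f"experiment {exp.label!r} observes {g!r}, "
                        f"which is not in the topology")
        if self.baseline is None:
            self.baseline = default_initial_guess(
                self.topology, self.experiments, self.channels)
        else:
            # complete missing per-experiment initial states: reuse the
            # "default" entry, else the first measurement, else 0.5
            for exp in self.experiments:
                states = self.baseline.initial_states.setdefault(exp.label, {})
                fallback = self.baseline.initial_states.get("default", {})
                for n in self.topology.nodes:
                    if n.id in states:
                        continue
                    if n.id in fallback:
                        states[n.id] = fallback[n.id]
                    elif n.id in exp.series:
                        states[n.id] = float(exp.series[n.id].values[0])
                    else:
                        states[n.id] = 0.5
        if not self.free_parameters:
            self.free_parameters = default_free_parameters(
                self.topology, self.experiments, self.channels)
        known = set(self.baseline.to_flat())
        unknown = [p for p in self.free_parameters if p not in known]
        if unknown:
            raise ParameterError(f"free parameters not in the model: {unknown}")
        for pid in self.free_parameters:
            lo, hi = self.bounds_for(pid)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(
                    f"free parameter {pid!r} needs finite bounds with lo < hi "
                    f"(got {lo}, {hi})")

    def bounds_for(self, pid: str) -> tuple[float, float]:
        if pid in self.bounds:
            return self.bounds[pid]
        return DEFAULT_BOUNDS[_id_kind(pid)]

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = [], []
        for pid in self.free_parameters:
            lo, hi = self.bounds_for(pid)
            los.append(lo)
            his.append(hi)
        return np.asarray(los), np.asarray(his)

    def with_values(self, vector: np.ndarray) -> ParameterSet:
        params = self.baseline.copy()
        for pid, v in zip(self.free_parameters, vector):
            params.set_flat(pid, float(v))
        return params

    def vector_of(self, params: ParameterSet) -> np.ndarray:
        flat = params.to_flat()
        return np.array([flat[pid] for pid in self.free_parameters])


def default_free_parameters(topology: Topology,
                            experiments: Sequence[Experiment],
                            channels: Sequence[StimulusChannel] = (),
                            include_x0: bool = True) -> list[str]:
    """All edge weights, steepnesses and couplings; x0 per experiment.

    Decays are excluded: they stay fixed at 1 so activity levels remain in
    [0, 1] without state constraints.
    """
    free: list[str] = []
    for e in topology.edges:
        prefix = "a" if e.sign == ACTIVATING else "b"
        free.append(f"{prefix}_{e.source}__{e.target}")
    for n in topology.non_constant_nodes():
        free.append(f"h_{n.id}")
    for ch in channels:
        free.append(f"d_{ch.id}")
    if include_x0:
        for exp in experiments:
            for n in topology.nodes:
                if n.kind != "constant":
                    free.append(f"x0_{exp.label}__{n.id}")
    return free


def default_initial_guess(topology: Topology,
                          experiments: Sequence[Experiment],
                          channels: Sequence[StimulusChannel] = ()) -> ParameterSet:
    """Uniform defaults; x0 starts at the first measured value where known."""
    params = ParameterSet()
    for e in topology.edges:
        table = (params.activator_weights if e.sign == ACTIVATING
                 else params.inhibitor_weights)
        table[(e.source, e.target)] = DEFAULT_INIT["a" if e.sign == ACTIVATING else "b"]
    for n in topology.non_constant_nodes():
        params.steepness[n.id] = DEFAULT_INIT["h"]
        params.decay[n.id] = DEFAULT_INIT["g"]
    for ch in channels:
        params.couplings[ch.id] = DEFAULT_INIT["d"]
    for exp in experiments:
        states = {}
        for n in topology.nodes:
            s = exp.series.get(n.id)
            states[n.id] = float(s.values[0]) if s is not None else 0.5
        params.initial_states[exp.label] = states
    return params


@dataclass
class FitResult:
    params: ParameterSet
    chi2_total: float
    per_observable: dict[tuple[str, str], float]   # (experiment, gene) -> chi2
    n_data: int
    n_free: int
    diagnostics: dict = field(default_factory=dict)
    start_chi2: list[float] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _experiment_residuals(problem: FitProblem, exp: Experiment,
                          params: ParameterSet) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Weighted residuals for one experiment plus their (label, gene) tags."""
    times = exp.measurement_times()
    t_eval = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    traj = simulate(problem.topology, params, profile=exp.profile,
                    t_eval=t_eval, channels=tuple(problem.channels),
                    experiment=exp.label, rtol=problem.rtol, atol=problem.atol)
    t_index = {float(t): i for i, t in enumerate(traj.times)}
    residuals: list[float] = []
    tags: list[tuple[str, str]] = []
    for gene, s in exp.series.items():
        col = traj.node_ids.index(gene)
        sigma = s.sigma(exp.use_sem)
        for t, x_data, sig in zip(s.times, s.values, sigma):
            if sig <= 0:
                raise DataError(f"{exp.label}/{gene}: sigma <= 0 at t={t}")
            x_model = traj.states[t_index[float(t)], col]
            residuals.append((x_model - x_data) / sig)
            tags.append((exp.label, gene))
    return np.asarray(residuals), tags


def chi_square(problem: FitProblem, params: ParameterSet
               ) -> tuple[float, dict[tuple[str, str], float], int]:
    """Total chi-square, per-(experiment, gene) breakdown, and data count.

    The total equals the sum of the breakdown exactly (same residuals).
    """
    breakdown: dict[tuple[str, str], float] = {}
    total = 0.0
    n_data = 0
    for exp in problem.experiments:
        res, tags = _experiment_residuals(problem, exp, params)
        n_data += len(res)
        for r, tag in zip(res, tags):
            breakdown[tag] = breakdown.get(tag, 0.0) + float(r) ** 2
        total += float(np.sum(res ** 2))
    # make the decomposition identity exact by construction
    total = float(sum(breakdown.values())) if breakdown else 0.0
    return total, breakdown, n_data


def count_free_parameters(problem: FitProblem) -> int:
    return len(problem.free_parameters)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def fit(problem: FitProblem, init: ParameterSet | None = None,
        max_nfev: int | None = None, xtol: float = 1e-10,
        ftol: float = 1e-10, gtol: float = 1e-10,
        start_index: int = 0) -> FitResult:
    """Bounded least squares from one starting point.

    Deterministic given the start; the returned chi-square never exceeds the
    starting chi-square (trust-region steps are accepted only on decrease).
    """
    if not problem.free_parameters:
        raise ConfigurationError("no free parameters to fit")
    if init is None:
        init = problem.baseline
    x_init = problem.vector_of(init)
    lo, hi = problem.bounds_arrays()
    if np.any(x_init < lo) or np.any(x_init > hi):
        raise ParameterError("initial guess lies outside the parameter box")

    def residual_fun(x: np.ndarray) -> np.ndarray:
        params = problem.with_values(x)
        chunks = [
            _experiment_residuals(problem, exp, params)[0]
            for exp in problem.experiments
        ]
        return np.concatenate(chunks) if chunks else np.zeros(0)

    try:
        sol = least_squares(residual_fun, x_init, bounds=(lo, hi), method="trf",
                            xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=max_nfev)
        converged = bool(sol.success)
        x_best, nfev, message = sol.x, sol.nfev, sol.message
    except Exception as exc:  # solver blow-up: report, don't crash the sweep
        converged = False
        x_best, nfev, message = x_init, 0, f"optimizer failure: {exc}"

    best = problem.with_values(np.clip(x_best, lo, hi))
    total, breakdown, n_data = chi_square(problem, best)
    return FitResult(
        params=best, chi2_total=total, per_observable=breakdown,
        n_data=n_data, n_free=len(problem.free_parameters),
        diagnostics={"converged": converged, "nfev": int(nfev),
                     "message": message, "start_index": start_index})


def fit_multistart(problem: FitProblem, n_starts: int, seed: int,
                   include_default: bool = False, **fit_kw) -> FitResult:
    """Best of ``n_starts`` fits from seeded Latin-hypercube starting points.

    Reproducible given the seed; the full start-by-start chi-square list is
    attached to the returned result.
    """
    if n_starts < 1:
        raise ConfigurationError("n_starts must be >= 1")
    lo, hi = problem.bounds_arrays()
    sampler = qmc.LatinHypercube(d=len(problem.free_parameters), seed=seed)
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    inits = [problem.with_values(row) for row in starts]
    if include_default:
        inits.insert(0, problem.baseline)
    best: FitResult | None = None
    chi2s: list[float] = []
    for i, init in enumerate(inits):
        result = fit(problem, init, start_index=i, **fit_kw)
        chi2s.append(result.chi2_total)
        if best is None or result.chi2_total < best.chi2_total:
            best = result
    best.start_chi2 = chi2s
    return best


def warm_start(problem: FitProblem,
               previous: "FitResult | ParameterSet | str",
               allow_sign_change: bool = False
               ) -> tuple[ParameterSet, dict[str, list[str]]]:
    """Initial guess carrying over shared parameters from a previous fit.

    Parameters present in both the previous result and the new problem keep
    their fitted values (clipped into the new box); new parameters get the
    default initial guesses.  An edge whose sign flipped between topologies
    is refused unless ``allow_sign_change`` — the old weight was estimated
    under the opposite regulatory role.
    """
    if isinstance(previous, FitResult):
        prev_params = previous.params
    elif isinstance(previous, ParameterSet):
        prev_params = previous
    else:
        prev_params, _, _ = read_parameter_table(previous)
    prev_flat = prev_params.to_flat()

    if not allow_sign_change:
        prev_pairs = {pid.split("_", 1)[1]: pid[0]
                      for pid in prev_flat if pid[:2] in ("a_", "b_")}
        for e in problem.topology.edges:
            pair = f"{e.source}__{e.target}"
            new_prefix = "a" if e.sign == ACTIVATING else "b"
            old_prefix = prev_pairs.get(pair)
            if old_prefix is not None and old_prefix != new_prefix:
                other = "a" if new_prefix == "b" else "b"
                if f"{new_prefix}_{pair}" not in prev_flat:
                    raise WarmStartError(
                        f"edge {e.source}->{e.target} changed sign since the "
                        f"previous fit ({other}_{pair} was fitted); carrying its "
                        f"weight over would be meaningless — refit it or pass "
                        f"allow_sign_change=True")

    init = problem.baseline.copy()
    carried, defaulted, clipped = [], [], []
    for pid in init.to_flat():
        if pid in prev_flat:
            value = prev_flat[pid]
            lo, hi = problem.bounds_for(pid)
            v_clipped = min(max(value, lo), hi)
            if v_clipped != value:
                clipped.append(pid)
            init.set_flat(pid, v_clipped)
            carried.append(pid)
        else:
            defaulted.append(pid)
    return init, {"carried": sorted(carried), "defaulted": sorted(defaulted),
                  "clipped": sorted(clipped)}
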