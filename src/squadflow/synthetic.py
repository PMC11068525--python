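"""Synthetic topologies, ground-truth parameters and noisy data.

Everything here is seeded and bit-reproducible; the generators write the
same formats the rest of the toolkit reads, so every pipeline stage can be
exercised end-to-end without external data.

Measurement noise is additive Gaussian on the normalized activity levels —
exactly the error model the chi-square objective assumes — except for
:func:`generate_counts`, which emulates the raw single-cell stage:
per-cell counts proportional to activity with multiplicative lognormal
noise and zero-inflation (dropouts).

Named fixtures at the bottom are the study conditions for the test suite:
a 3-gene recovery cascade, a bistable self-activation switch, a 1-gene
control toy with a brute-force-checkable optimum, and a 4-node two-channel
fixture whose two independent branches miniaturize a combination-therapy
synergy question (two stimuli, each able to fix exactly one target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .control import ControlProblem, DesiredState, Target
from .dataprep import SIGMA_FLOOR, CountMatrix, MeasurementSeries
from .dynamics import (ParameterSet, StimulusChannel, StimulusProfile,
                       default_parameters)
from .errors import ConfigurationError
from .fitting import Experiment
from .network import ACTIVATING, INHIBITING, Edge, Node, Topology
from .simulation import simulate


@dataclass
class SyntheticSpec:
    """Knobs for the random generators; the seed is mandatory."""

    n_genes: int
    seed: int
    edge_prob: float = 0.3
    activating_fraction: float = 0.7
    allow_self_loops: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("need at least one gene")
        for p in (self.edge_prob, self.activating_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0, 1]")


def generate_topology(spec: SyntheticSpec) -> Topology:
    """Random signed digraph; at least one regulated node when n >= 2."""
    rng = np.random.default_rng(spec.seed)
    names = [f"G{i + 1}" for i in range(spec.n_genes)]
    nodes = [Node(n) for n in names]
    edges: list[Edge] = []
    for src in names:
        for tgt in names:
            if src == tgt and not spec.allow_self_loops:
                continue
            if rng.random() < spec.edge_prob:
                sign = (ACTIVATING if rng.random() < spec.activating_fraction
                        else INHIBITING)
                edges.append(Edge(src, tgt, sign))
    if spec.n_genes >= 2 and not edges:
        edges.append(Edge(names[0], names[1], ACTIVATING))
    return Topology(nodes, edges).check()


def random_parameters(topology: Topology, seed: int,
                      channels: tuple[StimulusChannel, ...] = (),
                      experiments: tuple[str, ...] = ("default",),
                      weight_range: tuple[float, float] = (0.5, 3.0),
                      steepness_range: tuple[float, float] = (4.0, 12.0),
                      coupling_range: tuple[float, float] = (0.5, 2.0),
                      x0_range: tuple[float, float] = (0.05, 0.95)
                      ) -> ParameterSet:
    """Ground-truth parameters drawn uniformly inside sensible ranges."""
    rng = np.random.default_rng(seed)
    p = ParameterSet()
    for e in topology.edges:
        table = p.activator_weights if e.sign == ACTIVATING else p.inhibitor_weights
        table[(e.source, e.target)] = float(rng.uniform(*weight_range))
    for n in topology.non_constant_nodes():
        p.steepness[n.id] = float(rng.uniform(*steepness_range))
        p.decay[n.id] = 1.0
    for ch in channels:
        p.couplings[ch.id] = float(rng.uniform(*coupling_range))
    for exp in experiments:
        p.initial_states[exp] = {n.id: float(rng.uniform(*x0_range))
                                 for n in topology.nodes}
    return p


def generate_dataset(topology: Topology, truth: ParameterSet,
                     timepoints, noise_sd: float, seed: int,
                     label: str = "default",
                     profile: StimulusProfile | None = None,
                     channels: tuple[StimulusChannel, ...] = (),
                     observed: list[str] | None = None) -> Experiment:
    """Simulate the truth, sample it at ``timepoints`` and add Gaussian
    noise clipped to [0, 1]; the generating sigma is attached as the
    per-point dispersion (floored for the noise-free case)."""
    rng = np.random.default_rng(seed)
    timepoints = np.asarray(timepoints, dtype=float)
    t_eval = timepoints if timepoints[0] == 0.0 else np.concatenate([[0.0], timepoints])
    x0_key = label if label in truth.initial_states else "default"
    traj = simulate(topology, truth, profile=profile, t_eval=t_eval,
                    channels=channels, experiment=x0_key)
    keep = np.isin(traj.times, timepoints)
    genes = observed if observed is not None else [
        n.id for n in topology.non_constant_nodes()]
    sigma = max(noise_sd, SIGMA_FLOOR)
    series: dict[str, MeasurementSeries] = {}
    for g in genes:
        clean = traj.node(g)[keep]
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) \
            if noise_sd > 0 else clean.copy()
        noisy = np.clip(noisy, 0.0, 1.0)
        series[g] = MeasurementSeries(
            g, timepoints.copy(), noisy,
            np.full_like(noisy, sigma), np.full_like(noisy, sigma),
            np.ones(len(noisy), dtype=int))
    return Experiment(label, series, profile)


def generate_counts(topology: Topology, truth: ParameterSet,
                    timepoints, n_cells: int, dropout_p: float,
                    scale: float, seed: int,
                    lognormal_sigma: float = 0.25,
                    label: str = "default") -> list[CountMatrix]:
    """Zero-inflated per-cell count matrices emulating the raw single-cell
    input of the normalization front-end."""
    if n_cells < 2:
        raise ConfigurationError("need at least 2 cells per time point")
    rng = np.random.default_rng(seed)
    timepoints = np.asarray(timepoints, dtype=float)
    t_eval = timepoints if timepoints[0] == 0.0 else np.concatenate([[0.0], timepoints])
    traj = simulate(topology, truth, t_eval=t_eval, experiment=label)
    keep = np.isin(traj.times, timepoints)
    genes = [n.id for n in topology.non_constant_nodes()]
    matrices: list[CountMatrix] = []
    for pos, t in enumerate(timepoints):
        data = {}
        for g in genes:
            activity = traj.node(g)[keep][pos]
            noise = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_cells)
            counts = activity * scale * noise
            counts[rng.random(n_cells) < dropout_p] = 0.0
            data[g] = counts
        matrices.append(CountMatrix(float(t), pd.DataFrame(data)))
    return matrices


# ---------------------------------------------------------------------------
# Named fixtures (fixed seeds and conditions used throughout the tests)
# ---------------------------------------------------------------------------

def three_gene_recovery(noise_sd: float = 0.02, seed: int = 20240) -> tuple[
        Topology, ParameterSet, Experiment]:
    """3-gene cascade with a self-sustaining driver, for parameter recovery.

    G1 self-activates (holding its high initial state), drives G2, which
    drives G3; 8 time points over [0, 8] h with additive noise sigma=0.02.
    """
    topo = Topology(
        [Node("G1"), Node("G2"), Node("G3")],
        [Edge("G1", "G1", ACTIVATING),
         Edge("G1", "G2", ACTIVATING),
         Edge("G2", "G3", ACTIVATING)]).check()
    truth = ParameterSet(
        activator_weights={("G1", "G1"): 2.5, ("G1", "G2"): 2.0,
                           ("G2", "G3"): 2.0},
        inhibitor_weights={},
        steepness={"G1": 6.0, "G2": 6.0, "G3": 6.0},
        decay={"G1": 1.0, "G2": 1.0, "G3": 1.0},
        couplings={},
        initial_states={"default": {"G1": 0.9, "G2": 0.1, "G3": 0.1}})
    timepoints = np.linspace(0.5, 8.0, 8)
    experiment = generate_dataset(topo, truth, timepoints, noise_sd, seed)
    return topo, truth, experiment


def bistable_switch() -> tuple[Topology, ParameterSet]:
    """One self-activating gene with a steep response: two stable states.

    Started low it decays to 0; started high it rests near 1 — the minimal
    model of an expression switch.
    """
    topo = Topology([Node("G1")], [Edge("G1", "G1", ACTIVATING)]).check()
    params = ParameterSet(
        activator_weights={("G1", "G1"): 4.0},
        inhibitor_weights={},
        steepness={"G1": 10.0}, decay={"G1": 1.0}, couplings={},
        initial_states={"low": {"G1": 0.02}, "high": {"G1": 0.9}})
    return topo, params


def control_toy(alpha: float = 0.1) -> ControlProblem:
    """1-gene tracking toy: hold an unregulated (decaying) gene near 1.

    One up-channel with delta=1, theta=1 with weight 10, horizon 5,
    10 control segments, u_max=3.  Small enough for exhaustive search over
    constant controls, which makes it the solver's reference problem.
    """
    topo = Topology([Node("G1")], []).check()
    params = ParameterSet(
        activator_weights={}, inhibitor_weights={},
        steepness={"G1": 10.0}, decay={"G1": 1.0},
        couplings={"drive": 1.0},
        initial_states={"default": {"G1": 0.0}})
    channel = StimulusChannel("drive", "G1", "up")
    desired = DesiredState({"G1": Target(1.0, 10.0)})
    return ControlProblem(topo, params, [channel], desired,
                          horizon=5.0, alpha=alpha, n_segments=10, u_max=3.0)


def synergy_fixture(alpha: float = 0.1) -> ControlProblem:
    """Two independent driver->target branches, one up-channel per driver.

    Stimulating driver S1 rescues only target T1, S2 only T2; both targets
    carry desired value 1.  The miniature of the combination-therapy
    question: each single stimulus fixes exactly one read-out, only the
    pair fixes both.
    """
    topo = Topology(
        [Node("S1"), Node("T1", "output"), Node("S2"), Node("T2", "output")],
        [Edge("S1", "T1", ACTIVATING), Edge("S2", "T2", ACTIVATING)]).check()
    params = ParameterSet(
        activator_weights={("S1", "T1"): 3.0, ("S2", "T2"): 3.0},
        inhibitor_weights={},
        steepness={"S1": 8.0, "T1": 8.0, "S2": 8.0, "T2": 8.0},
        decay={n: 1.0 for n in ("S1", "T1", "S2", "T2")},
        couplings={"c1": 1.5, "c2": 1.5},
        initial_states={"default": {"S1": 0.0, "T1": 0.0,
                                    "S2": 0.0, "T2": 0.0}})
    channels = [StimulusChannel("c1", "S1", "up"),
                StimulusChannel("c2", "S2", "up")]
    desired = DesiredState({"T1": Target(1.0, 1.0), "T2": Target(1.0, 1.0)})
    return ControlProblem(topo, params, channels, desired,
                          horizon=6.0, alpha=alpha, n_segments=10, u_max=2.0)
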