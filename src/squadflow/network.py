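"""Signed regulatory topologies and graph-file I/O.

A topology is a signed directed graph. Nodes are genes, output nodes
(phenotype read-outs such as proliferation or apoptosis, dynamically
ordinary nodes) or constant nodes (clamped expression, no incoming edges).
Each edge is either activating or inhibiting; a pair of nodes may carry both
an activating and an inhibiting edge at once, but never two edges of the
same sign (a duplicate would create a redundant, unidentifiable weight).

Supported file formats are GraphML (as produced e.g. by yEd, with the sign
read from an explicit ``sign`` edge attribute or, as a fallback, from a
target-arrow style attribute) and a plain signed edge-list CSV with header
``source,target,sign``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import pandas as pd

from .errors import (
    GraphFormatError,
    LookupError_,
    SignResolutionError,
    TopologyValidationError,
)

ACTIVATING = "activating"
INHIBITING = "inhibiting"
Sign = Literal["activating", "inhibiting"]
Kind = Literal["gene", "output", "constant"]

NODE_KINDS = ("gene", "output", "constant")

_SIGN_ALIASES = {
    "+": ACTIVATING,
    "activating": ACTIVATING,
    "activation": ACTIVATING,
    "act": ACTIVATING,
    "-": INHIBITING,
    "−": INHIBITING,  # unicode minus
    "inhibiting": INHIBITING,
    "inhibition": INHIBITING,
    "inh": INHIBITING,
}

# yEd encodes regulation in the target arrowhead: spike-shaped arrows
# (standard/plain/delta) activate, t-shaped arrows inhibit.
_ARROW_STYLES = {
    "standard": ACTIVATING,
    "plain": ACTIVATING,
    "delta": ACTIVATING,
    "t_shape": INHIBITING,
    "t-shape": INHIBITING,
    "tee": INHIBITING,
}
_ARROW_KEYS = ("target_arrow", "targetarrow", "target_arrow_style", "arrowhead", "arrow")


def parse_sign(raw: str) -> Sign:
    try:
        return _SIGN_ALIASES[str(raw).strip().lower()]
    except KeyError:
        raise SignResolutionError(f"unrecognized edge sign {raw!r}") from None


@dataclass(frozen=True)
class Node:
    id: str
    kind: Kind = "gene"
    label: str | None = None


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: Sign

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.sign)


@dataclass
class Issue:
    """One validation finding: the offending element and the violated rule."""

    rule: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"[{self.rule}] {self.element}: {self.message}"


@dataclass
class Topology:
    """Validated signed regulatory graph.

    ``nodes`` preserves declaration order; that order fixes the state-vector
    layout everywhere downstream, so it must be deterministic.
    """

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {n.id: n for n in self.nodes}

    # -- access -------------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise LookupError_(f"unknown node {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._index

    def regulators_of(self, node_id: str) -> tuple[list[str], list[str]]:
        """Sources of activating and inhibiting in-edges, in input order."""
        self.node(node_id)
        activators = [e.source for e in self.edges
                      if e.target == node_id and e.sign == ACTIVATING]
        inhibitors = [e.source for e in self.edges
                      if e.target == node_id and e.sign == INHIBITING]
        return activators, inhibitors

    def activating_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.sign == ACTIVATING]

    def inhibiting_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.sign == INHIBITING]

    def non_constant_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.kind != "constant"]

    # -- validation ---------------------------------------------------------
    def validate(self) -> list[Issue]:
        return validate_topology(self)

    def check(self) -> "Topology":
        issues = self.validate()
        if issues:
            raise TopologyValidationError(issues)
        return self


def regulators_of(topology: Topology, node_id: str) -> tuple[list[str], list[str]]:
    return topology.regulators_of(node_id)


def validate_topology(topology: Topology) -> list[Issue]:
    """Collect all invariant violations; an empty list means valid.

    Issues are data, not exceptions — callers decide whether to raise.
    """
    issues: list[Issue] = []
    seen_ids: set[str] = set()
    for n in topology.nodes:
        if not n.id:
            issues.append(Issue("node-id", repr(n.id), "node id must be non-empty"))
        if n.id in seen_ids:
            issues.append(Issue("node-unique", n.id, "duplicate node id"))
        seen_ids.add(n.id)
        if n.kind not in NODE_KINDS:
            issues.append(Issue("node-kind", n.id, f"unknown kind {n.kind!r}"))

    kinds = {n.id: n.kind for n in topology.nodes}
    seen_edges: set[tuple[str, str, str]] = set()
    for e in topology.edges:
        name = f"{e.source}->{e.target} ({e.sign})"
        if e.source not in kinds:
            issues.append(Issue("edge-endpoint", name, f"undeclared source {e.source!r}"))
        if e.target not in kinds:
            issues.append(Issue("edge-endpoint", name, f"undeclared target {e.target!r}"))
        elif kinds[e.target] == "constant":
            issues.append(Issue("edge-into-constant", name,
                                "constant nodes cannot be regulated"))
        if e.sign not in (ACTIVATING, INHIBITING):
            issues.append(Issue("edge-sign", name, f"unknown sign {e.sign!r}"))
        if e.key in seen_edges:
            issues.append(Issue("edge-duplicate", name,
                                "duplicate same-signed edge"))
        seen_edges.add(e.key)
    return issues


def build_topology(nodes: Iterable[Node | str | tuple],
                   edges: Iterable[Edge | tuple]) -> Topology:
    """Convenience constructor accepting plain tuples; validates strictly."""
    norm_nodes: list[Node] = []
    for n in nodes:
        if isinstance(n, Node):
            norm_nodes.append(n)
        elif isinstance(n, str):
            norm_nodes.append(Node(n))
        else:
            norm_nodes.append(Node(*n))
    norm_edges: list[Edge] = []
    for e in edges:
        if isinstance(e, Edge):
            norm_edges.append(e)
        else:
            src, tgt, sign = e
            norm_edges.append(Edge(src, tgt, parse_sign(sign)))
    return Topology(norm_nodes, norm_edges).check()


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_graph(path, format: str | None = None) -> Topology:
    """Read a topology from GraphML or signed edge-list CSV.

    The format is inferred from the extension unless given explicitly.
    """
    path = str(path)
    if format is None:
        format = "graphml" if path.lower().endswith((".graphml", ".xml")) else "edgelist_csv"
    if format == "graphml":
        return _read_graphml(path)
    if format == "edgelist_csv":
        return _read_edgelist_csv(path)
    raise GraphFormatError(f"unknown graph format {format!r}")


def write_graph(topology: Topology, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "graphml" if path.lower().endswith((".graphml", ".xml")) else "edgelist_csv"
    if format == "graphml":
        _write_graphml(topology, path)
    elif format == "edgelist_csv":
        _write_edgelist_csv(topology, path)
    else:
        raise GraphFormatError(f"unknown graph format {format!r}")


def _resolve_sign(data: dict, source: str, target: str) -> Sign:
    if "sign" in data:
        return parse_sign(data["sign"])
    for key in _ARROW_KEYS:
        if key in data:
            style = str(data[key]).strip().lower()
            if style in _ARROW_STYLES:
                return _ARROW_STYLES[style]
            raise SignResolutionError(
                f"edge {source}->{target}: unknown arrow style {data[key]!r} "
                f"and no 'sign' attribute")
    raise SignResolutionError(
        f"edge {source}->{target}: no 'sign' attribute and no recognizable "
        f"arrow-style attribute")


def _read_graphml(path: str) -> Topology:
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:
        raise GraphFormatError(f"cannot parse GraphML file {path}: {exc}") from exc
    nodes = []
    for node_id, data in g.nodes(data=True):
        kind = str(data.get("kind", "gene"))
        label = data.get("label")
        nodes.append(Node(str(node_id), kind, label))
    edges = []
    for src, tgt, data in g.edges(data=True):
        edges.append(Edge(str(src), str(tgt), _resolve_sign(data, str(src), str(tgt))))
    return Topology(nodes, edges).check()


def _write_graphml(topology: Topology, path: str) -> None:
    g = nx.MultiDiGraph()
    for n in topology.nodes:
        attrs = {"kind": n.kind}
        if n.label is not None:
            attrs["label"] = n.label
        g.add_node(n.id, **attrs)
    for e in topology.edges:
        g.add_edge(e.source, e.target, sign=e.sign)
    nx.write_graphml(g, path)


def _read_edgelist_csv(path: str) -> Topology:
    try:
        df = pd.read_csv(path, dtype=str, comment="#")
    except Exception as exc:
        raise GraphFormatError(f"cannot parse edge-list CSV {path}: {exc}") from exc
    required = {"source", "target", "sign"}
    if not required.issubset(df.columns):
        raise GraphFormatError(
            f"edge-list CSV {path} must have columns source,target,sign "
            f"(got {list(df.columns)})")
    edges = [Edge(str(r.source).strip(), str(r.target).strip(), parse_sign(r.sign))
             for r in df.itertuples()]
    node_ids: list[str] = []
    if "kind" in df.columns:  # optional: node kinds may be declared on any row
        pass
    for e in edges:
        for nid in (e.source, e.target):
            if nid not in node_ids:
                node_ids.append(nid)
    nodes = [Node(nid) for nid in node_ids]
    return Topology(nodes, edges).check()


def _write_edgelist_csv(topology: Topology, path) -> None:
    df = pd.DataFrame(
        [(e.source, e.target, e.sign) for e in topology.edges],
        columns=["source", "target", "sign"],
    )
    if isinstance(path, io.TextIOBase):
        df.to_csv(path, index=False)
    else:
        df.to_csv(str(path), index=False)
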