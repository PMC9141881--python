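"""Information-flow graphs built from temporal fragmentation analysis.

For every nonzero-entropy time-t node (outputs and memory-after), the DIS
collections over the t-1 predictor pool (inputs and memory-before) at
theta = 1 identify which upstream nodes account for the downstream entropy.
An edge runs from each member of each DIS to the target; it is *necessary*
(black) when the member appears in every DIS for that target, and *possible*
(red) when redundant predictive sets leave causation unresolved.  Edge labels
carry the proportion of the target's entropy that the single source accounts
for on its own — which is 0 for the members of an XOR-encrypted pair even
though the pair is jointly fully predictive.

A substrate connectome can disambiguate redundant sets: any DIS containing a
member without a physical read->write link to the target is a coincidental
prediction and is removed.  Zero-entropy nodes never appear in the graph;
nonzero-entropy targets with no DIS at the chosen theta (possible for
stochastic or truncated recordings) are kept and flagged unexplained rather
than silently dropped.

*Flow complexity* is simply the total number of edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx

from .fragmentation import (
    SUBSET_CAP,
    THETA_TOL,
    DISCollection,
    SubsetEntropyCache,
    find_dis,
)
from .state_records import StateRecording, pair_states
from .substrates import Connectome

__all__ = [
    "FlowNode",
    "FlowEdge",
    "FlowGraph",
    "build_flow_graph",
    "disambiguate",
    "flow_complexity",
    "export_graph",
    "load_graphml",
]

ROLE_INPUT, ROLE_MEMORY, ROLE_OUTPUT = "input", "memory", "output"


@dataclass(frozen=True)
class FlowNode:
    id: str
    role: str  # input | memory | output
    entropy: float


@dataclass(frozen=True)
class FlowEdge:
    source: str      # t-1 node
    target: str      # t node
    proportion: float  # I(source; target) / H(target)
    necessary: bool

    @property
    def color(self) -> str:
        return "black" if self.necessary else "red"


@dataclass
class FlowGraph:
    theta: float
    nodes: dict[str, FlowNode]
    edges: list[FlowEdge]
    dis_by_target: dict[str, DISCollection] = field(default_factory=dict)
    unexplained: set[str] = field(default_factory=set)
    proportions: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def in_degree(self, target: str) -> int:
        return sum(1 for e in self.edges if e.target == target)

    def dis_to_json(self, path: str | Path) -> None:
        payload = {
            t: {
                "theta": c.theta,
                "entropy": c.feature_entropy,
                "sets": [list(s) for s in c.sets],
                "fragmentation": c.minimal_size,
            }
            for t, c in sorted(self.dis_by_target.items())
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _edges_from_dis(
    dis_by_target: dict[str, DISCollection],
    proportions: dict[tuple[str, str], float],
) -> list[FlowEdge]:
    edges = []
    for target, coll in sorted(dis_by_target.items()):
        necessary = coll.necessary_members
        for source in sorted(coll.all_members):
            edges.append(
                FlowEdge(
                    source=source,
                    target=target,
                    proportion=proportions.get((source, target), 0.0),
                    necessary=source in necessary,
                )
            )
    return edges


def build_flow_graph(
    rec: StateRecording,
    theta: float = 1.0,
    cap: int = SUBSET_CAP,
    allow_large: bool = False,
) -> FlowGraph:
    """Search, for each nonzero-entropy t node, the DISs over the t-1 pool.

    The predictor pool is inputs plus memory-before; targets are outputs
    plus memory-after.  Zero-entropy predictors are excluded up front: a
    qualifying set containing one would always be a reducible superset of
    the same set without it.
    """
    s = rec.schema
    if not (s.inputs or s.memory) or not (s.outputs or s.memory):
        raise ValueError("recording needs input/output/memory node groups")
    predictors = list(s.inputs) + list(s.memory)
    targets = list(s.outputs) + list(s.memory)
    table = pair_states(rec, predictors, targets)
    pred_q = [p + "@t-1" for p in predictors]
    targ_q = [t + "@t" for t in targets]
    cache = SubsetEntropyCache(table, pred_q + targ_q)

    h_pred = {p: cache.entropy([q]) for p, q in zip(predictors, pred_q)}
    h_targ = {t: cache.entropy([q]) for t, q in zip(targets, targ_q)}
    pool_q = [q for p, q in zip(predictors, pred_q) if h_pred[p] > THETA_TOL]

    def role_of(node: str) -> str:
        if node in s.inputs:
            return ROLE_INPUT
        if node in s.outputs:
            return ROLE_OUTPUT
        return ROLE_MEMORY

    dis_by_target: dict[str, DISCollection] = {}
    proportions: dict[tuple[str, str], float] = {}
    unexplained: set[str] = set()
    for t, tq in zip(targets, targ_q):
        h_y = h_targ[t]
        if h_y <= THETA_TOL:
            continue
        if not pool_q:  # every predictor is constant: nothing can explain t
            coll = DISCollection(tq, theta, [], h_y)
        else:
            coll = find_dis(
                table, pool_q, tq, theta, cap=cap, allow_large=allow_large, _cache=cache
            )
        coll = DISCollection(
            feature=t,
            theta=theta,
            sets=[tuple(m[: -len("@t-1")] for m in st) for st in coll.sets],
            feature_entropy=h_y,
        )
        dis_by_target[t] = coll
        if not coll.sets:
            unexplained.add(t)
        for source in sorted(coll.all_members):
            i_st = cache.shared([source + "@t-1"], tq)
            proportions[(source, t)] = min(1.0, i_st / h_y)

    edges = _edges_from_dis(dis_by_target, proportions)
    node_ids = {e.source for e in edges} | {e.target for e in edges}
    node_ids |= set(dis_by_target)  # keep unexplained targets visible
    nodes = {
        n: FlowNode(n, role_of(n), h_targ.get(n, 0.0) or h_pred.get(n, 0.0))
        for n in sorted(node_ids)
    }
    # prefer the t-side entropy for nodes seen on both sides, else the t-1 side
    for n in list(nodes):
        h = h_targ.get(n, 0.0)
        if h <= THETA_TOL:
            h = h_pred.get(n, 0.0)
        nodes[n] = FlowNode(n, role_of(n), h)
    return FlowGraph(
        theta=theta,
        nodes=nodes,
        edges=edges,
        dis_by_target=dis_by_target,
        unexplained=unexplained,
        proportions=proportions,
    )


def disambiguate(graph: FlowGraph, conn: Connectome) -> FlowGraph:
    """Remove coincidentally predictive DISs using the physical wiring.

    A DIS is removed iff any member lacks a physical link to the target;
    necessity is then recomputed, so a target left with one DIS gets all its
    edges promoted to necessary.  Redundancy that the connectome supports on
    all sides remains marked possible.  If pruning removes every DIS of a
    target, the target is flagged unexplained.
    """
    new_dis: dict[str, DISCollection] = {}
    unexplained = set(graph.unexplained)
    for target, coll in graph.dis_by_target.items():
        kept = [
            st for st in coll.sets if all(conn.supports(m, target) for m in st)
        ]
        new_dis[target] = replace(coll, sets=kept)
        if not kept:
            unexplained.add(target)
    edges = _edges_from_dis(new_dis, graph.proportions)
    keep_ids = {e.source for e in edges} | {e.target for e in edges} | set(new_dis)
    nodes = {n: fn for n, fn in graph.nodes.items() if n in keep_ids}
    return FlowGraph(
        theta=graph.theta,
        nodes=nodes,
        edges=edges,
        dis_by_target=new_dis,
        unexplained=unexplained,
        proportions=dict(graph.proportions),
    )


def flow_complexity(graph: FlowGraph) -> int:
    """Total number of edges (necessary plus possible) in the flow graph."""
    return graph.n_edges


# ---------------------------------------------------------------------------
# export

_ROLE_SHAPE = {ROLE_INPUT: "invtriangle", ROLE_MEMORY: "ellipse", ROLE_OUTPUT: "box"}


def _to_networkx(graph: FlowGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in sorted(graph.nodes):
        fn = graph.nodes[n]
        g.add_node(
            n,
            role=fn.role,
            entropy=round(fn.entropy, 12),
            unexplained=n in graph.unexplained,
        )
    for e in sorted(graph.edges, key=lambda e: (e.target, e.source)):
        g.add_edge(
            e.source,
            e.target,
            proportion=round(e.proportion, 12),
            necessary=e.necessary,
            color=e.color,
        )
    return g


def export_graph(graph: FlowGraph, path: str | Path, format: str = "dot") -> None:
    """Write the graph as DOT or GraphML with deterministic ordering.

    Necessity is encoded as edge color (black/red), the entropy proportion as
    an edge label, and node entropies as node labels.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_networkx(graph), path)
        return
    if format != "dot":
        raise ValueError(f"unknown format: {format!r} (use 'dot' or 'graphml')")
    lines = ["digraph information_flow {", "  rankdir=TB;"]
    for n in sorted(graph.nodes):
        fn = graph.nodes[n]
        warn = " (unexplained)" if n in graph.unexplained else ""
        lines.append(
            f'  "{n}" [label="{n}\\n{fn.entropy:.2f}{warn}", '
            f"shape={_ROLE_SHAPE[fn.role]}];"
        )
    for e in sorted(graph.edges, key=lambda e: (e.target, e.source)):
        lines.append(
            f'  "{e.source}" -> "{e.target}" '
            f'[label="{e.proportion:.2f}", color={e.color}];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def load_graphml(path: str | Path) -> FlowGraph:
    """Round-trip loader for GraphML exports (DIS collections are not part of
    the serialized form and come back empty)."""
    g = nx.read_graphml(Path(path))
    nodes = {
        n: FlowNode(n, d["role"], float(d["entropy"])) for n, d in g.nodes(data=True)
    }
    edges = [
        FlowEdge(u, v, float(d["proportion"]), bool(d["necessary"]))
        for u, v, d in g.edges(data=True)
    ]
    unexplained = {n for n, d in g.nodes(data=True) if d.get("unexplained")}
    proportions = {(e.source, e.target): e.proportion for e in edges}
    return FlowGraph(
        theta=1.0,
        nodes=nodes,
        edges=sorted(edges, key=lambda e: (e.target, e.source)),
        unexplained=unexplained,
        proportions=proportions,
    )
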