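"""Greedy dense-subgraph module detection (IPCA-style).

Modules are grown from high-weight seed vertices. The weight of an edge
is the number of common neighbours of its endpoints; a vertex's weight is
the sum of its incident edge weights, so heavy vertices sit in locally
dense neighbourhoods. A growing module K accepts a neighbouring vertex v
when its interaction probability IN_vK = (#edges between v and K)/|K|
reaches the threshold T_in and the induced subgraph K + v keeps diameter
at most d. Grown modules of at least ``min_size`` members are emitted.

Candidates with equal IN are ranked by the summed weight of their edges
into the module, so a vertex backed by a dense neighbourhood beats one
hanging on a stray bridge edge; remaining ties go to vertex weight, then
lexicographic ID, making the output deterministic.

By default an emitted module's members are removed from the seed queue
only, so they may still be absorbed into later modules (overlapping
modules); with ``overlap=False`` they are removed from the working graph
entirely and module memberships are disjoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import InputError

#: Default minimum interaction probability for extending a module.
DEFAULT_T_IN = 0.5
#: Default induced-subgraph diameter bound.
DEFAULT_DIAMETER = 2
#: Smallest module worth reporting (2 would be a bare edge).
DEFAULT_MIN_SIZE = 3


@dataclass
class Module:
    """One detected module: members plus induced edges."""

    module_id: int
    members: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    t_in: float
    d: int

    def __len__(self) -> int:
        return len(self.members)


def build_module_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected simple graph from a pair table (gene_a, gene_b columns)."""
    graph = nx.Graph()
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        if a == b:
            raise InputError(f"self-loop on {a!r}")
        graph.add_edge(a, b)
    return graph


def edge_weight(graph: nx.Graph, u, v) -> int:
    """Number of common neighbours of the endpoints of edge (u, v)."""
    if not graph.has_edge(u, v):
        raise InputError(f"({u!r}, {v!r}) is not an edge")
    return len(set(graph[u]) & set(graph[v]))


def vertex_weight(graph: nx.Graph, v) -> int:
    """Sum of the weights of the edges incident to v."""
    return sum(edge_weight(graph, v, u) for u in graph[v])


def interaction_probability(graph: nx.Graph, v, members) -> float:
    """Fraction of module members adjacent to candidate v."""
    members = set(members)
    if v in members:
        raise InputError(f"candidate {v!r} is already a member")
    if not members:
        raise InputError("module must be nonempty")
    return len(set(graph[v]) & members) / len(members)


def subgraph_diameter(graph: nx.Graph, nodes) -> float:
    """Diameter of the induced subgraph (math.inf if disconnected, 0 if singleton)."""
    nodes = set(nodes)
    if not nodes:
        raise InputError("node set must be nonempty")
    if len(nodes) == 1:
        return 0
    sub = graph.subgraph(nodes)
    diameter = 0
    for source in nodes:
        lengths = nx.single_source_shortest_path_length(sub, source)
        if len(lengths) < len(nodes):
            return math.inf
        diameter = max(diameter, max(lengths.values()))
    return diameter


def _grow(graph: nx.Graph, seed, weights: dict, t_in: float, d: int) -> set:
    """Greedily extend {seed} under the IN and diameter conditions.

    Candidates (neighbours of the module) are ranked by IN descending,
    ties by summed edge weight into the module, then vertex weight, then
    lexicographic ID; the first candidate satisfying both conditions is
    added and the scan repeats until no candidate qualifies.
    """
    members = {seed}
    while True:
        candidates = set()
        for m in members:
            candidates.update(graph[m])
        candidates -= members
        if not candidates:
            return members

        def rank(v):
            attachment = sum(
                edge_weight(graph, v, u) for u in set(graph[v]) & members
            )
            return (
                -interaction_probability(graph, v, members),
                -attachment,
                -weights[v],
                str(v),
            )

        scored = sorted(candidates, key=rank)
        added = False
        for v in scored:
            if interaction_probability(graph, v, members) < t_in:
                break  # sorted by IN: nothing further qualifies
            if subgraph_diameter(graph, members | {v}) <= d:
                members.add(v)
                added = True
                break
        if not added:
            return members


def ipca(
    graph: nx.Graph,
    t_in: float = DEFAULT_T_IN,
    d: int = DEFAULT_DIAMETER,
    min_size: int = DEFAULT_MIN_SIZE,
    overlap: bool = True,
) -> list[Module]:
    """Detect dense modules by seeded greedy expansion.

    Seeds are processed in order of vertex weight descending, ties broken
    by higher degree then lexicographic ID. After a module is emitted its
    members leave the seed queue but stay in the graph, so they may join
    later modules (set ``overlap=False`` to remove them from the graph
    and force disjoint memberships). Modules are numbered in emission
    order. Deterministic: identical input yields an identical module list.
    """
    if not 0 <= t_in <= 1:
        raise InputError("T_in must lie in [0, 1]")
    if d < 1 or min_size < 2:
        raise InputError("d must be >= 1 and min_size >= 2")
    work = graph.copy()
    weights = {v: vertex_weight(work, v) for v in work}
    queue = sorted(work, key=lambda v: (-weights[v], -work.degree(v), str(v)))
    clustered: set = set()
    modules: list[Module] = []
    for seed in queue:
        if seed in clustered:
            continue
        members = _grow(work, seed, weights, t_in, d)
        clustered |= members
        if len(members) >= min_size:
            induced = sorted(
                tuple(sorted((str(u), str(v))))
                for u, v in graph.subgraph(members).edges()
            )
            modules.append(
                Module(
                    module_id=len(modules) + 1,
                    members=tuple(sorted(members, key=str)),
                    edges=tuple(induced),
                    t_in=t_in,
                    d=d,
                )
            )
            if not overlap:
                work.remove_nodes_from(members)
    return modules
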