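"""MCODE dense-module detection (vertex weighting, complex prediction,
post-processing), following the published algorithm with the Cytoscape
plugin's default parameters: degree cutoff 2, node-score percentage 0.2,
haircut on, fluff off, k-core filter 2, max depth 100.

A vertex's weight is k * density of the highest k-core of its closed
neighborhood; complexes grow outward from the highest-weighted unvisited
seed, admitting neighbors whose weight is within the node-score
percentage of the seed's.  Ties in seeding and ranking are broken by the
lexicographically smallest node id so output is independent of input
ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .study import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class Complex:
    """A detected dense module: node set with score = density * size."""

    nodes: tuple
    score: float
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.nodes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weight(graph: nx.Graph, v) -> float:
    """k * density of the highest k-core of v's closed neighborhood."""
    if v not in graph:
        raise ValidationError(f"node {v!r} not in graph")
    nbhd = set(graph[v]) | {v}
    sub = graph.subgraph(nbhd)
    if sub.number_of_edges() == 0:
        return 0.0
    core = nx.core_number(sub)
    k_max = max(core.values())
    core_nodes = [u for u, c in core.items() if c >= k_max]
    return k_max * _density(sub.subgraph(core_nodes))


def find_complexes(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
    degree_cutoff: int = 2,
    kcore_filter: int = 2,
    max_depth: int = 100,
) -> list[Complex]:
    """Seeded greedy complex prediction with MCODE post-processing.

    Nodes below ``degree_cutoff`` are scored 0 and never seed or join a
    complex.  Each complex is grown breadth-first from the heaviest
    unvisited seed, admitting unvisited neighbors with weight >=
    seed_weight * (1 - vwp) up to ``max_depth``; members belong to at most
    one complex.  Haircut iteratively strips members with fewer than two
    within-complex neighbors; fluff optionally adds boundary nodes whose
    closed-neighborhood density exceeds ``fluff_density``.  Complexes
    whose induced subgraph lacks a ``kcore_filter``-core are discarded;
    survivors are ranked by score = density * size, descending.
    """
    if not (0.0 <= vwp <= 1.0):
        raise ValidationError("vwp must lie in [0, 1]")
    if graph.is_multigraph() or any(u == v for u, v in graph.edges):
        raise ValidationError("find_complexes expects a simple graph without self-loops")

    weights = {
        v: (vertex_weight(graph, v) if graph.degree(v) >= degree_cutoff else 0.0)
        for v in graph
    }
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    raw_complexes: list[set] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        cutoff = weights[seed] * (1.0 - vwp)
        members = {seed}
        visited.add(seed)
        frontier = [(seed, 0)]
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for u in sorted(graph[v], key=str):
                if u in visited or u in members:
                    continue
                if weights[u] >= cutoff:
                    members.add(u)
                    visited.add(u)
                    frontier.append((u, depth + 1))
        raw_complexes.append(members)

    complexes: list[Complex] = []
    for members in raw_complexes:
        members = set(members)
        if haircut:
            changed = True
            while changed and len(members) > 1:
                sub = graph.subgraph(members)
                trim = {v for v in members if sub.degree(v) < 2}
                changed = bool(trim)
                members -= trim
        if fluff:
            boundary = set()
            for v in sorted(members, key=str):
                for u in sorted(graph[v], key=str):
                    if u in members or u in boundary:
                        continue
                    nbhd = set(graph[u]) | {u}
                    if _density(graph.subgraph(nbhd)) > fluff_density:
                        boundary.add(u)
            members |= boundary
        if not members:
            continue
        sub = graph.subgraph(members)
        if sub.number_of_edges() == 0:
            continue
        if kcore_filter > 0 and max(nx.core_number(sub).values()) < kcore_filter:
            continue
        complexes.append(
            Complex(nodes=tuple(sorted(members, key=str)),
                    score=_density(sub) * len(members))
        )

    complexes.sort(key=lambda c: (-c.score, c.nodes))
    for i, c in enumerate(complexes, start=1):
        c.rank = i
    return complexes
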