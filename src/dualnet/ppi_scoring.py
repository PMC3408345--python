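"""Score-based module detection on an interaction network.

P-values on network nodes are modelled as a beta-uniform mixture (BUM),
f(p) = lambda + (1 - lambda) * a * p^(a-1), separating uniform noise from
signal concentrated near zero.  The mixture yields an FDR-controlled
P-value threshold tau and additive node scores (a - 1) * (ln p - ln tau)
that are positive exactly for p < tau.  Module detection then seeks the
maximum-weight connected subgraph: exactly by branch-and-bound on small
graphs, and by a Steiner-tree-style heuristic (connect positive
components through cheapest negative paths, then prune losing subtrees)
on larger ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .study import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class BUMFit:
    """Maximum-likelihood beta-uniform mixture fit to P-values."""

    lmbda: float
    a: float
    log_likelihood: float

    def density(self, p):
        p = np.asarray(p, float)
        return self.lmbda + (1.0 - self.lmbda) * self.a * p ** (self.a - 1.0)


def simplify_network(graph: nx.Graph) -> nx.Graph:
    """Collapse parallel edges and drop self-loops; node set unchanged."""
    simple = nx.Graph()
    simple.add_nodes_from(graph.nodes(data=True))
    simple.add_edges_from((u, v) for u, v in graph.edges() if u != v)
    return simple


def _clamp_pvalues(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, float)
    if np.any(p > 1) or np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if np.any(p <= 0):
        tiny = np.nextafter(0.0, 1.0)
        logger.warning("clamping %d zero p-value(s) to %g", int((p <= 0).sum()), tiny)
        p = np.where(p <= 0, tiny, p)
    return p


_BUM_STARTS = ((0.5, 0.5), (0.9, 0.1), (0.3, 0.3), (0.7, 0.7), (0.95, 0.5))
_BUM_BOUNDS = ((0.01, 0.99), (1e-3, 0.999))


def fit_bum(p_values) -> BUMFit:
    """Maximum-likelihood BUM fit via multi-start bounded quasi-Newton.

    lambda is kept inside [0.01, 0.99]: pure-uniform data puts the
    likelihood on a ridge where the mixture is unidentifiable, and the
    bound keeps the optimiser off it (the fitted signal mass
    (1-lambda)*(1-a) still vanishes there).
    """
    p = _clamp_pvalues(p_values)
    if len(p) < 100:
        raise ValidationError("need at least 100 p-values for a stable BUM fit")
    if np.ptp(p) == 0:
        raise ValidationError("all p-values identical; BUM fit undefined")
    logp = np.log(p)

    def nll(theta):
        lmbda, a = theta
        dens = lmbda + (1.0 - lmbda) * a * np.exp((a - 1.0) * logp)
        return -np.sum(np.log(dens))

    best = None
    for start in _BUM_STARTS:
        res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=_BUM_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    lmbda, a = best.x
    return BUMFit(lmbda=float(lmbda), a=float(a), log_likelihood=float(-best.fun))


def fdr_threshold(fit: BUMFit, fdr: float) -> float:
    """P-value threshold tau at which the mixture FDR equals ``fdr``.

    tau = (fdr*(1-lambda) / (pi - fdr*lambda))^(1/(1-a)) with
    pi = lambda + (1-lambda)*a the density at p = 1; clipped to <= 1.
    """
    if not (0 < fdr < 1):
        raise ValidationError("fdr must lie in (0, 1)")
    pi_hat = fit.lmbda + (1.0 - fit.lmbda) * fit.a
    denom = pi_hat - fdr * fit.lmbda
    if denom <= 0:
        raise ValidationError("requested FDR is unattainable for this fit")
    tau = (fdr * (1.0 - fit.lmbda) / denom) ** (1.0 / (1.0 - fit.a))
    return min(float(tau), 1.0)


def score_nodes(p_values: dict, fit: BUMFit, fdr: float) -> tuple[dict, float]:
    """Additive node scores (a-1)*(ln p - ln tau); positive iff p < tau."""
    tau = fdr_threshold(fit, fdr)
    nodes = list(p_values)
    p = _clamp_pvalues(np.array([p_values[v] for v in nodes], float))
    scores = (fit.a - 1.0) * (np.log(p) - math.log(tau))
    return dict(zip(nodes, scores.astype(float))), tau


def find_module_exact(graph: nx.Graph, scores: dict, max_nodes: int = 30) -> set:
    """Maximum-weight connected subgraph by branch-and-bound enumeration.

    Enumerates connected node subsets (each exactly once, rooted at its
    smallest node) with the bound current score + remaining positive
    scores.  Returns the empty set when no subset has strictly positive
    total; ties go to smaller, then lexicographically smaller sets.
    """
    if graph.number_of_nodes() > max_nodes:
        raise ValidationError(
            f"graph has {graph.number_of_nodes()} nodes (> {max_nodes}); "
            "use find_module_heuristic"
        )
    nodes = sorted(graph.nodes, key=str)
    s = {v: float(scores[v]) for v in nodes}
    best_score = 0.0
    best_set: tuple = ()

    def explore(current: set, score: float, ext: list, forbidden: set):
        nonlocal best_score, best_set
        if score > best_score + 1e-12:
            best_score = score
            best_set = tuple(sorted(current, key=str))
        bound = score + sum(s[v] for v in ext if s[v] > 0)
        # ext alone under-counts reachable positives; widen to all
        # non-forbidden positives outside the current set for a safe bound
        outside = [v for v in nodes
                   if v not in current and v not in forbidden and v not in ext and s[v] > 0]
        bound += sum(s[v] for v in outside)
        if bound <= best_score + 1e-12:
            return
        local_forbidden = set()
        for i, v in enumerate(ext):
            new_ext = [u for u in ext[i + 1:] if u not in local_forbidden]
            extra = [u for u in sorted(graph[v], key=str)
                     if u not in current and u not in forbidden
                     and u not in local_forbidden and u not in new_ext and u != v]
            explore(current | {v}, score + s[v], new_ext + extra,
                    forbidden | local_forbidden)
            local_forbidden.add(v)

    overall_forbidden: set = set()
    for root in nodes:
        ext0 = [u for u in sorted(graph[root], key=str) if u not in overall_forbidden]
        explore({root}, s[root], ext0, set(overall_forbidden))
        overall_forbidden.add(root)

    return set(best_set)


def _best_component(comps: list, s: dict) -> set:
    scored = [(sum(s[v] for v in c), -len(c), tuple(sorted(c, key=str))) for c in comps]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return set(scored[0][2])


def find_module_heuristic(graph: nx.Graph, scores: dict) -> set:
    """Steiner-style heuristic for the maximum-weight connected subgraph.

    Positive-score connected components are treated as terminals; a
    minimum spanning tree over their metric closure (path cost = summed
    deficit of intermediate negative nodes) proposes connections, and
    subtrees with negative total score are pruned.  The result is
    connected and never scores below the best single positive component.
    """
    s = {v: float(scores[v]) for v in graph.nodes}
    pos_nodes = [v for v in graph.nodes if s[v] > 0]
    if not pos_nodes:
        return set()
    comps = [set(c) for c in nx.connected_components(graph.subgraph(pos_nodes))]
    fallback = _best_component(comps, s)
    fallback_score = sum(s[v] for v in fallback)
    if len(comps) == 1:
        return fallback

    # edge-weighted proxy: traversing node v costs max(0, -s[v])
    H = nx.Graph()
    H.add_nodes_from(graph.nodes)
    cost = {v: max(0.0, -s[v]) for v in graph.nodes}
    for u, v in graph.edges:
        H.add_edge(u, v, w=(cost[u] + cost[v]) / 2.0)

    comp_of = {}
    for i, c in enumerate(comps):
        for v in c:
            comp_of[v] = i

    super_g = nx.Graph()
    super_g.add_nodes_from(range(len(comps)))
    paths_between: dict[tuple, list] = {}
    for i, c in enumerate(comps):
        try:
            dist, paths = nx.multi_source_dijkstra(H, c, weight="w")
        except nx.NetworkXNoPath:  # pragma: no cover - dijkstra returns reachable only
            dist, paths = {}, {}
        for j in range(i + 1, len(comps)):
            best = None
            for v in comps[j]:
                if v in dist and (best is None or dist[v] < best[0]):
                    best = (dist[v], v)
            if best is not None:
                key = (i, j)
                paths_between[key] = paths[best[1]]
                super_g.add_edge(i, j, weight=best[0])

    candidate: set = set()
    for tree_comp in nx.connected_components(super_g):
        for i in tree_comp:
            candidate |= comps[i]
    mst = nx.minimum_spanning_tree(super_g, weight="weight")
    for i, j in mst.edges:
        key = (min(i, j), max(i, j))
        candidate |= set(paths_between[key])

    sub = graph.subgraph(candidate)
    # keep only the connected piece containing the best component
    anchor = sorted(fallback, key=str)[0]
    piece = nx.node_connected_component(sub, anchor)
    sub = graph.subgraph(piece)

    # prune subtrees with non-positive total score on a BFS tree
    tree = nx.bfs_tree(sub, anchor)
    order = list(nx.dfs_postorder_nodes(tree, anchor))
    subtotal = {}
    removed: set = set()
    for v in order:
        total = s[v] + sum(subtotal[c] for c in tree.successors(v) if c not in removed)
        if total <= 0 and v != anchor:
            removed |= set(nx.descendants(tree, v)) | {v}
            subtotal[v] = 0.0
        else:
            subtotal[v] = total
    result = set(tree.nodes) - removed
    if sum(s[v] for v in result) < fallback_score:
        return fallback
    return result
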