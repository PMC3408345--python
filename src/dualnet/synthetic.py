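"""Seeded synthetic-data generators emulating a paired pre/post treatment study.

The generators produce every input the pipeline consumes: a paired
two-arm expression study with latent-factor co-expression modules, a
sex-marker gene and planted treatment-responsive genes; a scale-free
interaction network carrying beta-uniform node P-values with a planted
connected signal subgraph; random gene-set collections with planted sets;
and a single-rooted ontology DAG with upward-propagated annotations.

All draws are reproducible from a single integer seed per call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .study import ExpressionStudy, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StudyTruth:
    """Ground truth planted into a synthetic expression study."""

    de_genes: set
    module_assignments: dict  # gene_id -> module index (0 = background)
    marker_gene: str
    effect_size: float
    arm_of_subject: dict  # subject_id -> "treated" | "placebo"

    def to_json_dict(self) -> dict:
        return {
            "de_genes": sorted(self.de_genes),
            "module_assignments": dict(sorted(self.module_assignments.items())),
            "marker_gene": self.marker_gene,
            "effect_size": self.effect_size,
            "arm_of_subject": dict(sorted(self.arm_of_subject.items())),
        }


@dataclass
class NetworkTruth:
    """Ground truth planted into a synthetic scored interaction network."""

    signal_nodes: set
    bum_lambda: float
    bum_a: float

    def to_json_dict(self) -> dict:
        return {
            "signal_nodes": sorted(self.signal_nodes),
            "bum_lambda": self.bum_lambda,
            "bum_a": self.bum_a,
        }


def generate_study(
    n_subjects: int = 32,
    n_genes: int = 2000,
    module_sizes: tuple = (150,),
    within_module_corr: float = 0.8,
    effect_size: float = 1.0,
    n_de_genes: int = 100,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionStudy, StudyTruth]:
    """Simulate a paired pre/post two-arm study with planted structure.

    Each subject contributes a ``pre`` and a ``post`` sample.  The
    post-minus-pre difference of a gene in module *m* follows the factor
    model ``delta = noise_sd * (sqrt(r) * f_m + sqrt(1-r) * eps)`` with
    ``f_m`` a per-subject module factor and ``r = within_module_corr``, so
    the expected pairwise correlation of baseline-corrected profiles within
    a module equals ``r`` exactly.  Treatment-responsive genes additionally
    shift by ``effect_size`` (log2 units) in the treated arm only.  One
    gene slot is reserved for a sex-marker expressed high in females
    (N(10, 1)) and low in males (N(5, 0.5)).
    """
    if seed is None:
        raise ValidationError("seed is required")
    if n_subjects <= 0 or n_genes <= 0:
        raise ValidationError("n_subjects and n_genes must be positive")
    if n_subjects % 2 != 0:
        raise ValidationError("n_subjects must be even (two equal arms)")
    if any(m < 2 for m in module_sizes):
        raise ValidationError("every module needs at least 2 genes")
    if sum(module_sizes) + 1 > n_genes:
        raise ValidationError(
            f"sum(module_sizes)+1 = {sum(module_sizes) + 1} exceeds n_genes = {n_genes}"
            " (one slot is reserved for the sex-marker gene)"
        )
    if not (0.0 <= within_module_corr < 1.0):
        raise ValidationError("within_module_corr must lie in [0, 1)")
    if n_de_genes > n_genes - 1:
        raise ValidationError("n_de_genes exceeds available (non-marker) genes")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]

    arms = np.array(["treated"] * (n_subjects // 2) + ["placebo"] * (n_subjects // 2))
    rng.shuffle(arms)
    sexes = np.array(["F", "M"] * (n_subjects // 2))
    rng.shuffle(sexes)
    ages = rng.integers(18, 66, size=n_subjects)

    # module assignment: first sum(module_sizes) genes, then the marker slot
    assignment = {g: 0 for g in genes}
    cursor = 0
    for m_idx, size in enumerate(module_sizes, start=1):
        for g in genes[cursor : cursor + size]:
            assignment[g] = m_idx
        cursor += size
    marker = genes[cursor]

    de_candidates = [g for g in genes if g != marker]
    de_genes = set(
        rng.choice(de_candidates, size=n_de_genes, replace=False)
    ) if n_de_genes else set()

    mu = rng.uniform(6.0, 12.0, size=n_genes)
    pre = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_subjects))

    r = within_module_corr
    eps = rng.normal(0.0, 1.0, size=(n_genes, n_subjects))
    factors = rng.normal(0.0, 1.0, size=(max(len(module_sizes), 1), n_subjects))
    delta = np.empty((n_genes, n_subjects))
    for i, g in enumerate(genes):
        m = assignment[g]
        if m > 0:
            delta[i] = noise_sd * (np.sqrt(r) * factors[m - 1] + np.sqrt(1.0 - r) * eps[i])
        else:
            delta[i] = noise_sd * eps[i]
    # treatment effect on responsive genes, treated arm only
    treated_mask = arms == "treated"
    de_idx = [i for i, g in enumerate(genes) if g in de_genes]
    if de_idx:
        delta[np.ix_(de_idx, np.where(treated_mask)[0])] += effect_size

    post = pre + delta

    # sex-marker overrides: high in females, low in males, per sample
    m_i = genes.index(marker)
    for arr in (pre, post):
        female = sexes == "F"
        arr[m_i, female] = rng.normal(10.0, 1.0, size=int(female.sum()))
        arr[m_i, ~female] = rng.normal(5.0, 0.5, size=int((~female).sum()))

    sample_ids, rows, cols = [], [], []
    for j, s in enumerate(subjects):
        for tp, arr in (("pre", pre), ("post", post)):
            sample_ids.append(f"{s}_{tp}")
            rows.append(
                {"subject_id": s, "timepoint": tp, "arm": arms[j],
                 "sex": sexes[j], "age": int(ages[j])}
            )
            cols.append(arr[:, j])

    matrix = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    samples = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    study = ExpressionStudy(matrix, samples)
    truth = StudyTruth(
        de_genes=de_genes,
        module_assignments=assignment,
        marker_gene=marker,
        effect_size=effect_size,
        arm_of_subject=dict(zip(subjects, arms)),
    )
    return study, truth


def generate_planted_network(
    n_nodes: int = 1000,
    edges_per_node: int = 3,
    signal_size: int = 30,
    bum_lambda: float = 0.9,
    bum_a: float = 0.2,
    seed: int = 0,
) -> tuple[nx.Graph, dict, NetworkTruth]:
    """Scale-free interaction graph with beta-uniform node P-values.

    The graph is a preferential-attachment (Barabasi-Albert) graph.  A
    connected signal subgraph of ``signal_size`` nodes is grown by seeded
    breadth-first search from a random start; signal nodes draw P-values
    from Beta(``bum_a``, 1).  The remaining non-uniform mixture mass
    ``(1 - bum_lambda) * n_nodes - signal_size`` (if positive) is assigned
    to randomly chosen background nodes so the pooled P-values follow
    ``bum_lambda * U(0,1) + (1 - bum_lambda) * Beta(bum_a, 1)`` at the
    requested parameters.  With ``signal_size == 0`` all P-values are
    uniform (degenerate no-signal case).
    """
    if not (0 < bum_lambda < 1) or not (0 < bum_a < 1):
        raise ValidationError("bum_lambda and bum_a must lie in (0, 1)")
    if signal_size >= n_nodes:
        raise ValidationError("signal_size must be smaller than n_nodes")
    if edges_per_node < 1 or edges_per_node >= n_nodes:
        raise ValidationError("edges_per_node out of range")

    rng = np.random.default_rng(seed)
    raw = nx.barabasi_albert_graph(n_nodes, edges_per_node,
                                   seed=int(rng.integers(2**31 - 1)))
    width = max(4, len(str(n_nodes)))
    mapping = {i: f"v{i:0{width}d}" for i in raw.nodes}
    graph = nx.relabel_nodes(raw, mapping)
    nodes = sorted(graph.nodes)

    n_beta = int(round((1.0 - bum_lambda) * n_nodes))
    if signal_size > 0 and n_beta < signal_size:
        raise ValidationError(
            "mixture is inconsistent: (1-bum_lambda)*n_nodes < signal_size"
        )

    signal: list = []
    if signal_size > 0:
        start = nodes[int(rng.integers(n_nodes))]
        frontier = [start]
        seen = {start}
        while frontier and len(signal) < signal_size:
            v = frontier.pop(0)
            signal.append(v)
            for u in sorted(graph[v]):
                if u not in seen:
                    seen.add(u)
                    frontier.append(u)
        if len(signal) < signal_size:  # BA graphs are connected; defensive
            raise ValidationError("could not grow a connected signal subgraph")

    pvals = {v: float(p) for v, p in zip(nodes, rng.uniform(size=n_nodes))}
    beta_nodes = list(signal)
    if signal_size > 0:
        background = [v for v in nodes if v not in set(signal)]
        extra = n_beta - signal_size
        if extra > 0:
            beta_nodes += list(rng.choice(background, size=extra, replace=False))
    for v in beta_nodes:
        pvals[v] = float(rng.beta(bum_a, 1.0))

    truth = NetworkTruth(signal_nodes=set(signal), bum_lambda=bum_lambda, bum_a=bum_a)
    return graph, pvals, truth


def generate_genesets(
    universe: list,
    n_sets: int,
    size_range: tuple = (5, 25),
    planted_sets: dict | None = None,
    categories: dict | None = None,
    seed: int = 0,
):
    """Random gene sets drawn from ``universe``, plus verbatim planted sets."""
    from .enrichment import GeneSetCollection

    planted_sets = dict(planted_sets or {})
    categories = dict(categories or {})
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValidationError("invalid size_range")
    if n_sets > 0 and hi > len(universe):
        raise ValidationError("size_range exceeds universe size")
    uni = set(universe)
    for name, members in planted_sets.items():
        stray = set(members) - uni
        if stray:
            raise ValidationError(f"planted set {name!r} has genes outside universe: {sorted(stray)[:5]}")

    rng = np.random.default_rng(seed)
    universe_sorted = sorted(universe)
    sets: dict[str, frozenset] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe_sorted, size=size, replace=False)
        sets[f"RS{i + 1:03d}"] = frozenset(members.tolist())
    for name, members in planted_sets.items():
        sets[name] = frozenset(members)
    return GeneSetCollection(sets=sets, categories=categories, name="synthetic")


def generate_dag(
    n_terms: int,
    max_parents: int = 2,
    annotations_per_term: tuple = (3, 10),
    universe: list = (),
    seed: int = 0,
):
    """Single-rooted acyclic term graph with upward-propagated annotations.

    Term ``i > 0`` picks 1..max_parents parents among terms ``0..i-1``, so
    the graph is acyclic and every term reaches the root ``T000``.  Each
    term draws its own annotated genes; a parent's annotation set is the
    union of its own genes and all descendants' sets.
    """
    from .enrichment import OntologyDAG

    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if max_parents < 1:
        raise ValidationError("max_parents must be >= 1")
    lo, hi = annotations_per_term
    rng = np.random.default_rng(seed)
    universe_sorted = sorted(universe)
    terms = [f"T{i:03d}" for i in range(n_terms)]

    parents: dict[str, frozenset] = {terms[0]: frozenset()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        idx = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = frozenset(terms[j] for j in idx)

    own: dict[str, set] = {}
    for t in terms:
        if universe_sorted and hi > 0:
            size = int(rng.integers(lo, hi + 1))
            size = min(size, len(universe_sorted))
            own[t] = set(rng.choice(universe_sorted, size=size, replace=False).tolist())
        else:
            own[t] = set()

    full = {t: set(own[t]) for t in terms}
    for i in range(n_terms - 1, 0, -1):
        for p in parents[terms[i]]:
            full[p] |= full[terms[i]]

    annotations = {t: frozenset(full[t]) for t in terms}
    return OntologyDAG(parents=parents, annotations=annotations)


def sample_power_law_degrees(
    n: int, gamma: float, xmin: int = 1, kmax: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Draw integer degrees from the discrete power law P(k) ~ k^-gamma, k >= xmin."""
    rng = np.random.default_rng(seed)
    k = np.arange(xmin, kmax + 1, dtype=float)
    w = k ** (-gamma)
    cdf = np.cumsum(w / w.sum())
    u = rng.uniform(size=n)
    return (np.searchsorted(cdf, u) + xmin).astype(int)
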