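"""Hypergeometric over-representation analysis, DAG-conditional testing,
pathway filtering, and term clustering.

ORA uses the upper-tail hypergeometric P(X >= k) for the overlap k of a
query list (size n) with an annotated set (size K) inside a universe of N
genes.  The conditional variant walks an ontology DAG children-first and,
before testing a term, removes genes already explained by its significant
descendants.  Pathway filtering reproduces a disease-category exclusion
(with named exceptions), a minimum-supporting-gene rule, and the
drop-modules-without-surviving-annotations rule; term clustering orders
pathways by average-linkage hierarchical clustering under the
1 - Pearson distance on per-module gene counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .study import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set category labels."""

    sets: dict  # name -> frozenset of gene ids
    categories: dict = field(default_factory=dict)  # name -> label
    name: str = "collection"

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}

    def restrict_to_universe(self, universe) -> "GeneSetCollection":
        uni = set(universe)
        restricted = {}
        for term, members in self.sets.items():
            stray = members - uni
            if stray:
                logger.info("dropping %d gene(s) of %s outside the universe", len(stray), term)
            restricted[term] = frozenset(members & uni)
        return GeneSetCollection(restricted, dict(self.categories), self.name)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class OntologyDAG:
    """Acyclic child->parent term graph with per-term gene annotations.

    Invariant: a parent's annotation set contains the union of its
    children's (annotations propagate upward).
    """

    parents: dict  # term -> frozenset of parent terms
    annotations: dict  # term -> frozenset of gene ids

    def __post_init__(self) -> None:
        self.parents = {t: frozenset(p) for t, p in self.parents.items()}
        self.annotations = {t: frozenset(g) for t, g in self.annotations.items()}
        dangling = {p for ps in self.parents.values() for p in ps} - set(self.parents)
        if dangling:
            raise ValidationError(f"dangling parent references: {sorted(dangling)}")
        self._order = self._topological_children_first()
        for child, ps in self.parents.items():
            for p in ps:
                if not self.annotations.get(child, frozenset()) <= self.annotations.get(p, frozenset()):
                    raise ValidationError(
                        f"annotations of {child!r} not contained in parent {p!r}"
                    )

    @property
    def terms(self) -> list:
        return list(self.parents)

    def children_map(self) -> dict:
        children: dict = {t: set() for t in self.parents}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].add(child)
        return children

    def _topological_children_first(self) -> list:
        # Kahn's algorithm on child -> parent edges: children come first
        out_deg = {t: len(self.children_map()[t]) for t in self.parents}
        children = self.children_map()
        ready = sorted(t for t, d in out_deg.items() if d == 0)
        order = []
        remaining = dict(out_deg)
        while ready:
            t = ready.pop(0)
            order.append(t)
            for p in sorted(self.parents[t]):
                remaining[p] -= 1
                if remaining[p] == 0:
                    ready.append(p)
            ready.sort()
        if len(order) != len(self.parents):
            raise ValidationError("cycle detected in ontology DAG")
        return order

    def topological_order(self) -> list:
        """Terms ordered children before parents."""
        return list(self._order)

    def descendants(self, term) -> set:
        children = self.children_map()
        seen: set = set()
        stack = list(children[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(children[t])
        return seen

    def roots(self) -> list:
        return sorted(t for t, ps in self.parents.items() if not ps)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(k, n, K, N) < 0:
        raise ValidationError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(gene_list, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """One hypergeometric test per set; table sorted by P then term."""
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    query = set(gene_list)
    stray = query - uni
    if stray:
        logger.warning("dropping %d query gene(s) outside the universe", len(stray))
        query &= uni
    n, N = len(query), len(uni)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & uni
        hits = sorted(query & members)
        rows.append((term, len(hits), n, len(members), N,
                     ",".join(hits), collection.categories.get(term, "")))
    if rows:
        k_arr = np.array([r[1] for r in rows])
        K_arr = np.array([r[3] for r in rows])
        with np.errstate(invalid="ignore"):
            p_arr = stats.hypergeom.sf(k_arr - 1, N, K_arr, n)
        p_arr = np.where(k_arr == 0, 1.0, p_arr)
        p_arr = np.clip(p_arr, np.nextafter(0.0, 1.0), 1.0)
    else:
        p_arr = np.array([])
    table = pd.DataFrame(
        {
            "term": [r[0] for r in rows],
            "k": [r[1] for r in rows],
            "n": [r[2] for r in rows],
            "K": [r[3] for r in rows],
            "N": [r[4] for r in rows],
            "p_value": p_arr,
            "genes": [r[5] for r in rows],
            "category": [r[6] for r in rows],
        }
    ).sort_values(["p_value", "term"], kind="stable", ignore_index=True)
    table.attrs["collection"] = collection.name
    return table


def conditional_ora(gene_list, dag: OntologyDAG, universe, alpha: float = 0.05) -> pd.DataFrame:
    """DAG-conditional ORA, children before parents.

    Before testing a term, genes annotated to its already-significant
    (p < alpha) descendants are removed from both the term's annotation
    set and the query overlap, so a parent is only credited for evidence
    its significant children do not explain.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    query = set(gene_list) & uni
    n, N = len(query), len(uni)
    significant: set = set()
    rows = []
    for term in dag.topological_order():
        ann = dag.annotations[term] & uni
        removed = set()
        for d in dag.descendants(term):
            if d in significant:
                removed |= dag.annotations[d]
        eff = ann - removed
        k = len(query & eff)
        K = len(eff)
        p = hypergeom_test(k, n, K, N) if (K and n and k <= min(n, K)) else 1.0
        if p < alpha:
            significant.add(term)
        rows.append((term, k, n, K, N, p, ",".join(sorted(query & eff))))
    table = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_value", "genes"]
    ).sort_values(["p_value", "term"], kind="stable", ignore_index=True)
    table.attrs["collection"] = "ontology"
    return table


def filter_pathways(
    tables: dict,
    excluded_categories=("disease",),
    exceptions=("Asthma",),
    min_support: int = 2,
) -> tuple[dict, list]:
    """Category- and support-based pathway filtering across modules.

    Per module: drop terms in an excluded category unless named in
    ``exceptions``, and drop terms supported by fewer than ``min_support``
    genes in that module.  A module is retained only if at least one of
    its genes is annotated in a term that survived filtering in some
    module.  Idempotent.
    """
    excluded = set(excluded_categories)
    excepted = set(exceptions)
    filtered = {}
    for module, table in tables.items():
        keep = table[
            (~table["category"].isin(excluded) | table["term"].isin(excepted))
            & (table["k"] >= min_support)
        ]
        filtered[module] = keep.reset_index(drop=True)
        filtered[module].attrs.update(table.attrs)
    surviving_terms = set().union(*(set(t["term"]) for t in filtered.values())) \
        if filtered else set()
    retained = []
    for module, table in tables.items():
        in_surviving = table[table["term"].isin(surviving_terms)]
        if (in_surviving["k"] >= 1).any():
            retained.append(module)
    return filtered, retained


def cluster_terms(count_matrix: pd.DataFrame):
    """Average-linkage clustering of terms under the 1 - Pearson distance.

    Rows are terms, columns module gene counts.  Constant rows get the
    maximal distance (2.0) to every other term.  Returns the ordered term
    list and the SciPy linkage (merge-tree) matrix.
    """
    if count_matrix.shape[0] < 2:
        raise ValidationError("need at least 2 terms to cluster")
    X = count_matrix.to_numpy(float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        logger.warning("%d constant term profile(s) assigned maximal distance",
                       int((sd == 0).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    dist = 1.0 - corr
    dist[~np.isfinite(dist)] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(linkage)
    return [count_matrix.index[i] for i in order], linkage
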