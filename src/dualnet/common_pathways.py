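"""Cross-network integration: shared enriched pathways and their
permutation null.

Two modules derived from independent networks each yield an enrichment
table; a pathway is "common" when significant in both after the standard
pathway filters.  Its chance level is estimated empirically: draw two
random gene lists of the observed module sizes from the universe, rerun
the identical enrichment + filtering + intersection, and report
P = n / N over N iterations (with the resolution floor 1/N noted and an
optional (n+1)/(N+1) corrected estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, filter_pathways, ora
from .study import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CommonPathwaysResult:
    """Per-term permutation counts and empirical P-values."""

    counts: dict  # term -> number of iterations in which it was common
    n_iterations: int
    size_a: int
    size_b: int
    alpha: float
    seed: int

    @property
    def p(self) -> dict:
        return {t: n / self.n_iterations for t, n in self.counts.items()}

    @property
    def p_corrected(self) -> dict:
        """Add-one estimate (n+1)/(N+1), bounded away from the 1/N floor."""
        return {t: (n + 1) / (self.n_iterations + 1) for t, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, n, self.n_iterations, n / self.n_iterations,
             (n + 1) / (self.n_iterations + 1))
            for t, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["term", "n", "N", "p", "p_corrected"])


def common_terms(table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05) -> set:
    """Terms significant (p < alpha) in both enrichment tables."""
    coll_a = table_a.attrs.get("collection")
    coll_b = table_b.attrs.get("collection")
    if coll_a and coll_b and coll_a != coll_b:
        raise ValidationError(
            f"enrichment tables come from different collections: {coll_a!r} vs {coll_b!r}"
        )
    sig_a = set(table_a.loc[table_a["p_value"] < alpha, "term"])
    sig_b = set(table_b.loc[table_b["p_value"] < alpha, "term"])
    return sig_a & sig_b


def permutation_p(
    universe,
    size_a: int,
    size_b: int,
    collection: GeneSetCollection,
    target_terms,
    n_iterations: int = 1000,
    alpha: float = 0.05,
    min_support: int = 2,
    excluded_categories=(),
    exceptions=(),
    seed: int = 0,
) -> CommonPathwaysResult:
    """Size-matched permutation null for common pathways, P = n / N.

    Each iteration draws two gene lists independently and without
    replacement from the universe, reruns ORA, applies the same pathway
    filters as the observed analysis, intersects the significant terms of
    both lists, and counts hits for each target term.
    """
    universe = sorted(set(universe))
    if size_a > len(universe) or size_b > len(universe):
        raise ValidationError("list size exceeds universe")
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {t: 0 for t in target_terms}
    zero_floor_logged = False
    for _ in range(n_iterations):
        list_a = rng.choice(universe, size=size_a, replace=False)
        list_b = rng.choice(universe, size=size_b, replace=False)
        table_a = ora(list_a, collection, universe)
        table_b = ora(list_b, collection, universe)
        filtered, _ = filter_pathways(
            {"A": table_a, "B": table_b},
            excluded_categories=excluded_categories,
            exceptions=exceptions,
            min_support=min_support,
        )
        common = common_terms(filtered["A"], filtered["B"], alpha=alpha)
        for t in counts:
            if t in common:
                counts[t] += 1
    for t, n in counts.items():
        if n == 0 and not zero_floor_logged:
            logger.info("zero permutation hits reported as p = 0; resolution floor is 1/%d",
                        n_iterations)
            zero_floor_logged = True
    return CommonPathwaysResult(
        counts=counts, n_iterations=n_iterations, size_a=size_a, size_b=size_b,
        alpha=alpha, seed=seed,
    )
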