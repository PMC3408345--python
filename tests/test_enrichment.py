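"""Hypergeometric ORA, conditional DAG testing, filtering, clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from dualnet import enrichment as enr
from dualnet import synthetic
from dualnet.enrichment import GeneSetCollection, OntologyDAG
from dualnet.study import ValidationError


def _hypergeom_enumeration(k, n, K, N):
    """Sampling-free enumeration of the upper tail via binomial coefficients."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(n, K) + 1)) / total


class TestHypergeomTest:
    def test_worked_example(self):
        assert enr.hypergeom_test(4, 5, 5, 20) == pytest.approx(76 / 15504, rel=1e-12)

    def test_trivial_tails(self):
        assert enr.hypergeom_test(0, 5, 5, 20) == 1.0
        assert enr.hypergeom_test(5, 5, 5, 5) == 1.0

    def test_inconsistent_counts(self):
        for args in ((6, 5, 5, 20), (1, 5, 5, 4), (-1, 5, 5, 20)):
            with pytest.raises(ValidationError):
                enr.hypergeom_test(*args)

    def test_equals_enumeration_oracle_full_grid(self):
        """Exhaustive agreement with the combinatorial oracle for N <= 25."""
        for N in range(1, 26):
            for n in range(0, N + 1):
                for K in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        got = enr.hypergeom_test(k, n, K, N)
                        want = _hypergeom_enumeration(k, n, K, N)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12), \
                            (k, n, K, N)


@pytest.fixture()
def small_collection():
    uni = [f"g{i:02d}" for i in range(30)]
    sets = {
        "S_hit": frozenset(uni[:6]),
        "S_other": frozenset(uni[10:20]),
        "S_disease": frozenset(uni[3:9]),
    }
    return uni, GeneSetCollection(sets, categories={"S_disease": "disease"},
                                  name="toy")


class TestOra:
    def test_planted_set_ranks_first(self):
        uni = [f"g{i}" for i in range(60)]
        coll = synthetic.generate_genesets(uni, n_sets=12, size_range=(5, 12),
                                           planted_sets={"PL": uni[:8]}, seed=2)
        table = enr.ora(uni[:8], coll, uni)
        assert table.iloc[0]["term"] == "PL"
        assert table.iloc[0]["k"] == 8

    def test_disjoint_list_all_p_one(self, small_collection):
        uni, coll = small_collection
        table = enr.ora(uni[20:25], GeneSetCollection({"S": frozenset(uni[:5])}),
                        uni)
        assert (table["p_value"] == 1.0).all()

    def test_duplicates_deduplicated(self, small_collection):
        uni, coll = small_collection
        t1 = enr.ora(uni[:4] * 3, coll, uni)
        t2 = enr.ora(uni[:4], coll, uni)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_universe_rejected(self, small_collection):
        _, coll = small_collection
        with pytest.raises(ValidationError):
            enr.ora(["g01"], coll, [])


class TestConditionalOra:
    def _chain_dag(self, parent_extra=()):
        child_genes = frozenset({"a", "b", "c", "d", "e"})
        parent_genes = child_genes | frozenset(parent_extra)
        return OntologyDAG(
            parents={"P": frozenset(), "C": frozenset({"P"})},
            annotations={"P": parent_genes, "C": child_genes},
        )

    def test_parent_conditioned_away(self):
        dag = self._chain_dag()
        uni = [c for c in "abcdefghijklmnopqrst"]
        table = enr.conditional_ora(list("abcd"), dag, uni, alpha=0.05).set_index("term")
        assert table.loc["C", "p_value"] < 0.05
        assert table.loc["P", "p_value"] == 1.0  # no genes left after conditioning

    def test_alpha_zero_equals_plain_ora(self):
        dag = self._chain_dag(parent_extra={"f", "g"})
        uni = [c for c in "abcdefghijklmnopqrst"]
        cond = enr.conditional_ora(list("abcd"), dag, uni, alpha=0.0).set_index("term")
        for term, ann in dag.annotations.items():
            want = enr.hypergeom_test(len(set("abcd") & ann), 4, len(ann), 20)
            assert cond.loc[term, "p_value"] == pytest.approx(want)

    def test_conditioning_never_lowers_ancestor_p(self):
        uni = [f"g{i}" for i in range(50)]
        dag = synthetic.generate_dag(12, max_parents=2,
                                     annotations_per_term=(3, 8), universe=uni,
                                     seed=9)
        query = sorted(dag.annotations[dag.topological_order()[0]])[:6]
        cond = enr.conditional_ora(query, dag, uni).set_index("term")
        sig = set(cond.index[cond["p_value"] < 0.05])
        for term in dag.terms:
            if dag.descendants(term) & sig:
                ann = dag.annotations[term]
                plain = enr.hypergeom_test(len(set(query) & ann), len(set(query) & set(uni)),
                                           len(ann), 50)
                assert cond.loc[term, "p_value"] >= plain - 1e-12

    def test_cycle_detected(self):
        with pytest.raises(ValidationError):
            OntologyDAG(parents={"A": frozenset({"B"}), "B": frozenset({"A"})},
                        annotations={"A": frozenset(), "B": frozenset()})


def _table(rows):
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N",
                                     "p_value", "genes", "category"])
    df.attrs["collection"] = "toy"
    return df


class TestFilterPathways:
    def test_min_support_and_category_rules(self):
        tables = {
            "M1": _table([("Asthma", 3, 10, 5, 100, 0.01, "a,b,c", "disease"),
                          ("OtherDisease", 3, 10, 5, 100, 0.01, "a,b,c", "disease"),
                          ("Weak", 1, 10, 5, 100, 0.01, "a", ""),
                          ("Good", 2, 10, 5, 100, 0.02, "a,b", "")]),
        }
        filtered, retained = enr.filter_pathways(
            tables, excluded_categories=("disease",), exceptions=("Asthma",))
        terms = set(filtered["M1"]["term"])
        assert terms == {"Asthma", "Good"}
        assert retained == ["M1"]

    def test_module_without_surviving_annotation_dropped(self):
        tables = {
            "M1": _table([("T1", 3, 10, 5, 100, 0.01, "a,b,c", "")]),
            "M2": _table([("T2", 1, 10, 5, 100, 0.5, "z", "")]),
        }
        filtered, retained = enr.filter_pathways(tables)
        assert retained == ["M1"]
        assert filtered["M2"].empty

    def test_idempotent(self):
        tables = {
            "M1": _table([("T1", 3, 10, 5, 100, 0.01, "a,b,c", ""),
                          ("T2", 1, 10, 5, 100, 0.5, "z", "x")]),
        }
        once, r1 = enr.filter_pathways(tables)
        twice, r2 = enr.filter_pathways(once)
        pd.testing.assert_frame_equal(once["M1"], twice["M1"])
        assert r1 == r2 == ["M1"]


class TestClusterTerms:
    def test_identical_profiles_merge_first(self):
        counts = pd.DataFrame([[1, 5, 2], [1, 5, 2], [9, 0, 4], [2, 2, 2]],
                              index=["A", "B", "C", "D"], columns=["m1", "m2", "m3"])
        order, linkage = enr.cluster_terms(counts)
        assert linkage[0][2] == pytest.approx(0.0, abs=1e-12)  # A and B merge at 0
        pos = {t: i for i, t in enumerate(order)}
        assert abs(pos["A"] - pos["B"]) == 1

    def test_anticorrelated_distance_two(self):
        counts = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                              index=["A", "B"], columns=["m1", "m2", "m3"])
        _, linkage = enr.cluster_terms(counts)
        assert linkage[0][2] == pytest.approx(2.0)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 9, size=(8, 4)),
                              index=[f"T{i}" for i in range(8)],
                              columns=[f"m{i}" for i in range(4)])
        o1, l1 = enr.cluster_terms(counts)
        o2, l2 = enr.cluster_terms(counts)
        assert o1 == o2
        assert np.allclose(l1, l2)

    def test_single_term_rejected(self):
        with pytest.raises(ValidationError):
            enr.cluster_terms(pd.DataFrame([[1, 2]], index=["A"]))
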