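"""Readers and writers for the pipeline's plain-text formats.

All files are UTF-8, tab-separated.  Readers validate their schema and
report offending line numbers; ``write`` then ``read`` is the identity on
valid objects.

Formats: expression matrix TSV (gene rows, sample columns), sample
annotation TSV, 3-column edge-list TSV (node_a, node_b, weight), GraphML,
GMT gene sets (name, description, genes...), ontology DAG as child/parent
TSV plus term/gene annotation TSV, and generic results TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import GeneSetCollection, OntologyDAG
from .study import SAMPLE_COLUMNS, DeltaMatrix, ExpressionStudy, ValidationError

logger = logging.getLogger(__name__)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        for i, (gene, row) in enumerate(df.iterrows(), start=2):
            if pd.to_numeric(row, errors="coerce").isna().any():
                raise ValidationError(f"{path}:{i}: non-numeric value for gene {gene!r}") from exc
        raise
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"age": int})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: annotation columns missing: {missing}")
    return df


def write_annotations(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_study(matrix_path, annotations_path) -> ExpressionStudy:
    return ExpressionStudy(read_expression(matrix_path), read_annotations(annotations_path))


def write_study(study: ExpressionStudy, matrix_path, annotations_path) -> None:
    write_expression(study.matrix, matrix_path)
    write_annotations(study.samples, annotations_path)


def read_edgelist(path, simple: bool = True) -> nx.Graph:
    g = nx.Graph() if simple else nx.MultiGraph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() and not header.startswith("node_a"):
            raise ValidationError(f"{path}:1: expected header 'node_a<TAB>node_b<TAB>weight'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 tab-separated fields")
            a, b, w = fields
            try:
                w = float(w)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from None
            if a == b:
                if simple:
                    raise ValidationError(f"{path}:{lineno}: self-loop on {a!r} in a simple graph")
                logger.warning("%s:%d: self-loop on %r", path, lineno, a)
            g.add_edge(a, b, weight=w)
    return g


def write_edgelist(graph: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{v}\t{data.get('weight', 1)}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    sets: dict = {}
    categories: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields (name, description, genes)"
                )
            term, description = fields[0], fields[1]
            if term in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {term!r}")
            sets[term] = frozenset(fields[2:])
            if description:
                categories[term] = description
    return GeneSetCollection(sets=sets, categories=categories,
                             name=name or Path(path).stem)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.sets):
            desc = collection.categories.get(term, "")
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n" if genes else f"{term}\t{desc}\t\n")


def read_dag(edges_path, annotations_path) -> OntologyDAG:
    parents: dict = {}
    with open(edges_path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term"):
            raise ValidationError(f"{edges_path}:1: expected header 'term<TAB>parent'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{edges_path}:{lineno}: expected 2 fields")
            term, parent = fields
            parents.setdefault(term, set())
            if parent:
                parents[term].add(parent)
    annotations: dict = {t: set() for t in parents}
    with open(annotations_path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term"):
            raise ValidationError(f"{annotations_path}:1: expected header 'term<TAB>gene'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"{annotations_path}:{lineno}: expected 2 fields")
            term, gene = fields
            if term not in annotations:
                raise ValidationError(
                    f"{annotations_path}:{lineno}: annotation for unknown term {term!r}"
                )
            annotations[term].add(gene)
    return OntologyDAG(parents=parents, annotations=annotations)


def write_dag(dag: OntologyDAG, edges_path, annotations_path) -> None:
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("term\tparent\n")
        for term in sorted(dag.parents):
            ps = sorted(dag.parents[term])
            if not ps:
                fh.write(f"{term}\t\n")
            for p in ps:
                fh.write(f"{term}\t{p}\n")
    with open(annotations_path, "w", encoding="utf-8") as fh:
        fh.write("term\tgene\n")
        for term in sorted(dag.annotations):
            for g in sorted(dag.annotations[term]):
                fh.write(f"{term}\t{g}\n")


def write_results(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
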