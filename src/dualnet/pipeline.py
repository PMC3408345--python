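"""End-to-end orchestration of the dual-network analysis.

The workflow mirrors a two-arm paired treatment study analysed three
ways from one baseline-corrected expression matrix: (i) per-gene
moderated-t differential expression, (ii) a calibrated
mutual-information co-expression network mined for dense modules, and
(iii) an interaction network scored from P-values and mined for a
maximum-weight connected subgraph.  Enriched pathways of the two modules
are filtered, intersected, and the shared pathways receive a
size-matched permutation P-value.  Every stage writes its table and a
JSON provenance record into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import coexnet, common_pathways, diffexpr, enrichment, io, mcode, ppi_scoring, preprocess, synthetic
from .study import ValidationError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Parameters and paths for a full pipeline run.

    With ``synthetic`` set (a dict of generator overrides) all inputs are
    simulated; otherwise the four input paths must point to existing
    files.  ``mi_p_cutoff=None`` picks a Bonferroni-style cutoff
    0.05 / (number of gene pairs), appropriate when the tested panel is
    far smaller than a genome-wide study.
    """

    outdir: str = "dualnet_out"
    seed: int = 0
    # inputs (file mode)
    expression: str | None = None
    annotations: str | None = None
    ppi_edgelist: str | None = None
    genesets_gmt: str | None = None
    dag_edges: str | None = None
    dag_annotations: str | None = None
    marker_gene: str | None = None
    negative_sex: str = "M"
    # synthetic mode
    synthetic: dict | None = None
    # statistical operating points
    alpha: float = 0.05
    fdr: float = 0.05
    mi_p_cutoff: float | None = None  # None: 0.05 / n_pairs; genome-scale runs use e.g. 1e-8
    kernel_width: float | None = None  # None -> calibrate at the observed sample size
    dpi: bool = True
    dpi_tolerance: float = 0.0
    bootstrap_cycles: int = 100
    consensus_q: float = 0.001
    permutation_N: int = 1000
    min_support: int = 2
    excluded_categories: tuple = ()
    exceptions: tuple = ()

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.fdr < 1):
            raise ValidationError("alpha and fdr must lie in (0, 1)")
        if self.mi_p_cutoff is not None and not (0 < self.mi_p_cutoff <= 1):
            raise ValidationError("mi_p_cutoff must lie in (0, 1]")
        if self.permutation_N < 1:
            raise ValidationError("permutation_N must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("excluded_categories", "exceptions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_categories"] = list(self.excluded_categories)
        d["exceptions"] = list(self.exceptions)
        return d


DEFAULT_SYNTHETIC = dict(
    n_subjects=32,
    n_genes=300,
    module_sizes=(40,),
    within_module_corr=0.8,
    effect_size=1.0,
    n_de_genes=30,
    noise_sd=1.0,
    ppi_nodes=250,
    ppi_edges_per_node=3,
    signal_size=20,
    bum_a=0.1,
    n_random_sets=20,
    set_size_range=(10, 30),
)


def _synthesize_inputs(cfg: PipelineConfig, outdir: Path):
    """Generate study, interaction network, and gene sets sharing one universe."""
    params = dict(DEFAULT_SYNTHETIC)
    params.update(cfg.synthetic or {})
    seed = cfg.seed
    study, truth = synthetic.generate_study(
        n_subjects=params["n_subjects"], n_genes=params["n_genes"],
        module_sizes=tuple(params["module_sizes"]),
        within_module_corr=params["within_module_corr"],
        effect_size=params["effect_size"], n_de_genes=params["n_de_genes"],
        noise_sd=params["noise_sd"], seed=seed,
    )
    n_ppi = min(params["ppi_nodes"], params["n_genes"] - 1)
    bum_lambda = 1.0 - params["signal_size"] / n_ppi
    graph, pvals, net_truth = synthetic.generate_planted_network(
        n_nodes=n_ppi, edges_per_node=params["ppi_edges_per_node"],
        signal_size=params["signal_size"], bum_lambda=bum_lambda,
        bum_a=params["bum_a"], seed=seed + 1,
    )
    # interaction-network nodes are genes: relabel onto the expression universe
    genes = [g for g in study.genes if g != truth.marker_gene]
    mapping = dict(zip(sorted(graph.nodes), genes[:n_ppi]))
    graph = nx.relabel_nodes(graph, mapping)
    pvals = {mapping[v]: p for v, p in pvals.items()}
    net_truth.signal_nodes = {mapping[v] for v in net_truth.signal_nodes}

    module_genes = sorted(g for g, m in truth.module_assignments.items() if m == 1)
    signal_genes = sorted(net_truth.signal_nodes)
    rng = np.random.default_rng(seed + 2)
    half = max(2, len(module_genes) // 3)
    common_set = sorted(
        set(rng.choice(module_genes, size=min(half, len(module_genes)), replace=False))
        | set(rng.choice(signal_genes, size=max(2, len(signal_genes) // 2), replace=False))
    )
    planted = {
        "PW_MODULE": module_genes,
        "PW_SIGNAL": signal_genes,
        "PW_COMMON": common_set,
    }
    collection = synthetic.generate_genesets(
        universe=list(study.genes), n_sets=params["n_random_sets"],
        size_range=tuple(params["set_size_range"]), planted_sets=planted,
        categories={}, seed=seed + 3,
    )
    io.write_study(study, outdir / "expression.tsv", outdir / "samples.tsv")
    io.write_edgelist(graph, outdir / "ppi_edges.tsv")
    io.write_gmt(collection, outdir / "genesets.gmt")
    io.write_json(truth.to_json_dict(), outdir / "study_truth.json")
    io.write_json(net_truth.to_json_dict(), outdir / "network_truth.json")
    return study, truth.marker_gene, graph, pvals, collection, truth, net_truth


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns the summary report dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    t_start = time.time()

    def stage(name):
        logger.info("stage %-12s started (seed=%d)", name, cfg.seed)
        report["stages"][name] = {"started": time.time() - t_start}
        return name

    try:
        name = stage("inputs")
        if cfg.synthetic is not None:
            study, marker, ppi_graph, node_pvals, collection, truth, net_truth = \
                _synthesize_inputs(cfg, outdir)
        else:
            for attr in ("expression", "annotations", "ppi_edgelist", "genesets_gmt",
                         "marker_gene"):
                if getattr(cfg, attr) is None:
                    raise ValidationError(f"config requires {attr} unless synthetic mode is on")
            study = io.read_study(cfg.expression, cfg.annotations)
            ppi_graph = io.read_edgelist(cfg.ppi_edgelist)
            node_pvals = None
            collection = io.read_gmt(cfg.genesets_gmt)
            marker = cfg.marker_gene
            truth = net_truth = None
    except (ValidationError, OSError) as exc:
        raise StageError("inputs", str(exc)) from exc

    try:
        name = stage("preprocess")
        threshold = preprocess.estimate_background_threshold(study, marker, cfg.negative_sex)
        filtered = preprocess.filter_unexpressed(study, threshold)
        delta = preprocess.baseline_correct(filtered)
        report["background_threshold"] = threshold
        report["genes_after_filter"] = len(filtered.genes)
        report["n_subjects"] = delta.n_subjects
        io.write_expression(delta.matrix, outdir / "delta.tsv")
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    try:
        name = stage("diffexpr")
        fits = diffexpr.fit_linear_model(delta)
        de_table = diffexpr.moderate_and_test(fits)
        io.write_results(de_table.reset_index(), outdir / "de_table.tsv")
        de_genes = list(de_table.index[de_table["p_value"] < cfg.alpha])
        report["n_de_p"] = len(de_genes)
        report["n_de_q"] = int((de_table["q_value"] < cfg.fdr).sum())
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    try:
        name = stage("coexnet")
        n = delta.n_subjects
        h = cfg.kernel_width or coexnet.calibrate_kernel_width(
            n_samples=n, n_reps=5, seed=cfg.seed + 10)
        mi_cfg = coexnet.MIEstimatorConfig(kernel_width=h)
        null_fit = coexnet.calibrate_mi_threshold(n, 500, mi_cfg, seed=cfg.seed + 11)
        n_pairs = len(delta.genes) * (len(delta.genes) - 1) // 2
        p_cut = cfg.mi_p_cutoff if cfg.mi_p_cutoff is not None else 0.05 / n_pairs
        i0 = coexnet.threshold_for_p(null_fit, p_cut)
        if cfg.bootstrap_cycles >= 2:
            net = coexnet.bootstrap_consensus(delta, mi_cfg, i0, B=cfg.bootstrap_cycles,
                                              q_cutoff=cfg.consensus_q, seed=cfg.seed + 12)
        else:
            net = coexnet.build_network(delta, mi_cfg, i0, apply_dpi_flag=cfg.dpi,
                                        dpi_tolerance=cfg.dpi_tolerance)
        io.write_edgelist(net, outdir / "coexpression_network.tsv")
        degrees = [d for _, d in net.degree() if d > 0]
        try:
            plaw = coexnet.fit_power_law(degrees, method="mle")
            report["degree_gamma"] = plaw.gamma
        except ValidationError:
            report["degree_gamma"] = None
        report["mi_kernel_width"] = h
        report["mi_threshold"] = i0
        report["mi_p_cutoff"] = p_cut
        report["coexnet_nodes"] = sum(1 for _, d in net.degree() if d > 0)
        report["coexnet_edges"] = net.number_of_edges()
        io.write_json({"kernel_width": h, "null_alpha": null_fit.alpha,
                       "null_beta": null_fit.beta, "mi_threshold": i0,
                       "p_cutoff": p_cut, "seed": cfg.seed},
                      outdir / "coexnet_provenance.json")
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    try:
        name = stage("mcode")
        complexes = mcode.find_complexes(net)
        rows = [(c.rank, c.score, c.size, ",".join(c.nodes)) for c in complexes]
        io.write_results(pd.DataFrame(rows, columns=["rank", "score", "size", "genes"]),
                         outdir / "mcode_complexes.tsv")
        report["n_complexes"] = len(complexes)
        top_module = list(complexes[0].nodes) if complexes else []
        report["top_complex_size"] = len(top_module)
        if len(top_module) >= 2:
            mean_r, mean_abs_r = diffexpr.module_coherence(top_module, delta)
            report["top_complex_mean_spearman"] = mean_r
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    try:
        name = stage("ppi_scoring")
        ppi_simple = ppi_scoring.simplify_network(ppi_graph)
        if node_pvals is None:
            shared = [g for g in ppi_simple.nodes if g in de_table.index]
            if not shared:
                raise ValidationError("interaction network shares no genes with the study")
            ppi_simple = ppi_simple.subgraph(shared).copy()
            node_pvals = {g: float(de_table.loc[g, "p_value"]) for g in shared}
        bum = ppi_scoring.fit_bum(np.array(list(node_pvals.values())))
        scores, tau = ppi_scoring.score_nodes(node_pvals, bum, cfg.fdr)
        bionet_module = sorted(ppi_scoring.find_module_heuristic(ppi_simple, scores))
        score_table = pd.DataFrame(
            {"node": list(scores), "p": [node_pvals[v] for v in scores],
             "score": [scores[v] for v in scores]}
        ).sort_values(["p", "node"], ignore_index=True)
        io.write_results(score_table, outdir / "node_scores.tsv")
        io.write_results(pd.DataFrame({"gene": bionet_module}), outdir / "bionet_module.tsv")
        report["bum_lambda"] = bum.lmbda
        report["bum_a"] = bum.a
        report["score_tau"] = tau
        report["bionet_module_size"] = len(bionet_module)
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    try:
        name = stage("enrichment")
        universe = list(filtered.genes)
        coll = collection.restrict_to_universe(universe)
        table_top = enrichment.ora(top_module, coll, universe)
        table_bionet = enrichment.ora(bionet_module, coll, universe)
        filtered_tables, retained = enrichment.filter_pathways(
            {"mcode_top": table_top, "bionet": table_bionet},
            excluded_categories=cfg.excluded_categories,
            exceptions=cfg.exceptions, min_support=cfg.min_support,
        )
        for mod, tab in filtered_tables.items():
            io.write_results(tab, outdir / f"enrichment_{mod}.tsv")
        report["retained_modules"] = retained
        sig_terms = sorted(
            set().union(*(set(t.loc[t["p_value"] < cfg.alpha, "term"])
                          for t in filtered_tables.values()))
        )
        if len(sig_terms) >= 2:
            counts = pd.DataFrame(
                {mod: [int(tab.set_index("term")["k"].get(t, 0)) for t in sig_terms]
                 for mod, tab in filtered_tables.items()},
                index=sig_terms,
            )
            order, _ = enrichment.cluster_terms(counts)
            io.write_results(counts.loc[order].reset_index(names="term"),
                             outdir / "pathway_heatmap.tsv")
        report["n_significant_terms"] = len(sig_terms)
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    try:
        name = stage("common_pathways")
        common = sorted(common_pathways.common_terms(
            filtered_tables["mcode_top"], filtered_tables["bionet"], alpha=cfg.alpha))
        report["common_terms"] = common
        if common and top_module and bionet_module:
            perm = common_pathways.permutation_p(
                universe, len(top_module), len(bionet_module), coll, common,
                n_iterations=cfg.permutation_N, alpha=cfg.alpha,
                min_support=cfg.min_support,
                excluded_categories=cfg.excluded_categories,
                exceptions=cfg.exceptions, seed=cfg.seed + 20,
            )
            io.write_results(perm.to_frame(), outdir / "common_pathways.tsv")
            report["common_pathway_p"] = perm.p
    except ValidationError as exc:
        raise StageError(name, str(exc)) from exc

    report["wall_time_s"] = time.time() - t_start
    if truth is not None:
        planted_module = {g for g, m in truth.module_assignments.items() if m == 1}
        top = set(top_module)
        report["mcode_planted_jaccard"] = (
            len(top & planted_module) / len(top | planted_module) if top else 0.0
        )
        signal = set(net_truth.signal_nodes)
        found = set(bionet_module)
        report["bionet_planted_jaccard"] = (
            len(found & signal) / len(found | signal) if found else 0.0
        )
    io.write_json({"config": cfg.to_dict(), "report": {k: v for k, v in report.items()
                                                       if k != "stages"}},
                  outdir / "provenance.json")
    return report


def interferome_style_enrichment(hits: int, list_size: int, annotated: int,
                                 universe: int) -> float:
    """Hypergeometric over-representation with explicit population counts.

    Convenience wrapper for testing a gene list against an externally
    curated annotation (e.g. interferon-regulated genes) where the
    universe and annotated counts are quoted numbers rather than derived
    from data; the result is exact for the supplied counts but only as
    good as those counts (the population totals are approximate by
    construction).
    """
    return enrichment.hypergeom_test(hits, list_size, annotated, universe)
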