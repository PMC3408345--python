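import networkx as nx
import numpy as np
import pytest

from dualnet import coexnet, preprocess, synthetic


@pytest.fixture(scope="session")
def null_de_table():
    """Moderated-t table for a null study (no effect, no modules)."""
    from dualnet import diffexpr

    study, _ = synthetic.generate_study(
        n_subjects=30, n_genes=2000, module_sizes=(), within_module_corr=0.0,
        effect_size=0.0, n_de_genes=0, noise_sd=1.0, seed=21,
    )
    delta = preprocess.baseline_correct(study)
    return diffexpr.moderate_and_test(diffexpr.fit_linear_model(delta))


@pytest.fixture(scope="session")
def planted_module_consensus():
    """Bootstrap-consensus MI network over a 60-gene panel with one planted
    20-gene module (r = 0.8) and pure-noise background, plus the truth."""
    study, truth = synthetic.generate_study(
        n_subjects=30, n_genes=60, module_sizes=(20,), within_module_corr=0.8,
        effect_size=0.0, n_de_genes=0, noise_sd=1.0, seed=11,
    )
    delta = preprocess.baseline_correct(study)
    h = coexnet.calibrate_kernel_width(30, n_reps=5, seed=12)
    cfg = coexnet.MIEstimatorConfig(kernel_width=h)
    null_fit = coexnet.calibrate_mi_threshold(30, 500, cfg, seed=13)
    n_pairs = 60 * 59 // 2
    i0 = coexnet.threshold_for_p(null_fit, 0.05 / n_pairs)
    net = coexnet.bootstrap_consensus(delta, cfg, i0, B=100, q_cutoff=0.001, seed=14)
    module = {g for g, m in truth.module_assignments.items() if m == 1}
    return net, module, delta


@pytest.fixture(scope="session")
def planted_ppi():
    """Scale-free graph with a 15-node planted signal subgraph (a = 0.1)."""
    graph, pvals, truth = synthetic.generate_planted_network(
        n_nodes=200, edges_per_node=3, signal_size=15,
        bum_lambda=1 - 15 / 200, bum_a=0.1, seed=9,
    )
    return graph, pvals, truth


def random_scored_graph(seed: int, n: int = 12, p: float = 0.3, loc: float = -0.2):
    """An Erdos-Renyi graph with normal node scores, for solver comparisons."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    scores = {v: float(rng.normal(loc=loc)) for v in g}
    return g, scores
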