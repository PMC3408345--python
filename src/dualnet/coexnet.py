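"""Mutual-information co-expression network inference with calibration.

The estimator is the classic kernel-density MI used by ARACNE-style
methods: profiles are copula-transformed to rank-uniform scores, joint and
marginal densities are estimated with Gaussian kernels of a common width
h, and MI (in nats) is the sample average of log f2(x,y)/(f1(x) f1(y)).
Two calibrations accompany it: a kernel-width grid search minimising MSE
against the closed-form Gaussian MI -0.5*ln(1-rho^2), and a null-MI
survival fit ln P(MI > I0) = alpha + beta*I0 that converts a P-value
cutoff into an MI threshold.  Network construction applies the data
processing inequality (remove the weakest edge of each triangle) and an
optional bootstrap consensus with a Bonferroni-corrected binomial support
test.  A power-law fit of the degree distribution serves as the network
diagnostic used to pick the operating P-value cutoff.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .study import DeltaMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class MIEstimatorConfig:
    """Gaussian-kernel MI estimator settings.

    ``kernel_width`` is the kernel standard deviation on the normal-scores
    scale: copula (rank-uniform) inputs are mapped through the standard
    normal quantile function before kernel density estimation, which
    removes the boundary bias a bounded support would impose.  MI is
    reported in nats.
    """

    kernel_width: float = 0.2

    def __post_init__(self) -> None:
        if not (self.kernel_width > 0):
            raise ValidationError("kernel_width must be positive")


@dataclass
class NullFit:
    """Least-squares fit of the null-MI log-survival line at one sample size."""

    alpha: float
    beta: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (self.beta < 0):
            raise ValidationError("beta must be negative (decreasing survival)")


@dataclass
class PowerLawFit:
    gamma: float
    fit_method: str
    xmin: int


def copula_transform(data) -> np.ndarray:
    """Replace each row by mid-ranks scaled to (0, 1): rank/(n+1).

    Accepts a 2-D array, DataFrame, or :class:`DeltaMatrix`; invariant
    under monotone transforms of each row.
    """
    if isinstance(data, DeltaMatrix):
        data = data.matrix
    X = np.asarray(data, float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    n = X.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 samples for the copula transform")
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        if np.ptp(X[i]) == 0:
            logger.warning("row %d is constant; copula scores degenerate to 0.5", i)
        out[i] = stats.rankdata(X[i]) / (n + 1.0)
    return out[0] if single else out


def _normal_scores(u: np.ndarray) -> np.ndarray:
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValidationError("expected copula-scale input strictly inside (0, 1)")
    return stats.norm.ppf(u)


def _loo_kernel(z: np.ndarray, h: float) -> np.ndarray:
    """Leave-one-out Gaussian kernel matrix (zero diagonal)."""
    d = z[:, None] - z[None, :]
    k = np.exp(-(d * d) / (2.0 * h * h))
    np.fill_diagonal(k, 0.0)
    return k


def mutual_information(x, y, config: MIEstimatorConfig) -> float:
    """Gaussian-kernel MI estimate in nats (clipped below at 0).

    Copula-scale inputs are mapped to normal scores; joint and marginal
    densities are leave-one-out kernel estimates (normalisation constants
    cancel in the density ratio), and the first-order Jensen bias of the
    log of a noisy density, -Var(fhat)/(2 f^2), is corrected from the
    empirical variance of the kernel values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 samples")
    h = config.kernel_width
    n = len(x)
    m = n - 1
    kx = _loo_kernel(_normal_scores(x), h)
    ky = _loo_kernel(_normal_scores(y), h)
    kxy = kx * ky
    f2 = kxy.sum(axis=1) / m
    f1x = kx.sum(axis=1) / m
    f1y = ky.sum(axis=1) / m
    v2 = ((kxy**2).sum(axis=1) / m - f2**2) / m
    v1x = ((kx**2).sum(axis=1) / m - f1x**2) / m
    v1y = ((ky**2).sum(axis=1) / m - f1y**2) / m
    with np.errstate(divide="ignore", invalid="ignore"):
        term = (np.log(f2 / (f1x * f1y))
                + v2 / (2.0 * f2**2) - v1x / (2.0 * f1x**2) - v1y / (2.0 * f1y**2))
    mi = float(np.mean(term))
    return max(mi, 0.0) if np.isfinite(mi) else 0.0


def all_pairs_mi(U: np.ndarray, h: float, chunk: int = 64) -> np.ndarray:
    """Symmetric MI matrix for all row pairs of a copula-scale matrix.

    Same leave-one-out, Jensen-corrected estimator as
    :func:`mutual_information`, vectorised over gene pairs.
    """
    G, n = U.shape
    m = n - 1
    Z = _normal_scores(U)
    K = np.exp(-((Z[:, :, None] - Z[:, None, :]) ** 2) / (2.0 * h * h))  # G x n x n
    for g in range(G):
        np.fill_diagonal(K[g], 0.0)
    K2 = K**2
    f1 = K.sum(axis=2) / m  # G x n
    v1 = (K2.sum(axis=2) / m - f1**2) / m
    marg = np.log(f1) + v1 / (2.0 * f1**2)  # per-gene marginal term
    M = np.zeros((G, G))
    for a0 in range(0, G, chunk):
        a1 = min(a0 + chunk, G)
        f2 = np.einsum("ain,bin->abi", K[a0:a1], K, optimize=True) / m
        e2 = np.einsum("ain,bin->abi", K2[a0:a1], K2, optimize=True) / m
        v2 = (e2 - f2**2) / m
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (np.log(f2) + v2 / (2.0 * f2**2)
                    - marg[a0:a1, None, :] - marg[None, :, :])
        M[a0:a1] = np.nanmean(np.where(np.isfinite(term), term, np.nan), axis=2)
    M = np.where(np.isfinite(M), M, 0.0)
    M = np.maximum(M, 0.0)
    np.fill_diagonal(M, 0.0)
    return np.maximum(M, M.T)


def gaussian_mi(rho: float) -> float:
    """Closed-form MI of a bivariate Gaussian, -0.5*ln(1-rho^2) nats."""
    return -0.5 * math.log(1.0 - rho * rho)


def _draw_bivariate(rng, rho: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    return z1, rho * z1 + math.sqrt(1.0 - rho * rho) * z2


def calibrate_kernel_width(
    n_samples: int,
    width_grid=(0.1, 0.15, 0.2, 0.25, 0.3, 0.4),
    n_reps: int = 10,
    rho_grid=(0.0, 0.3, 0.6, 0.9),
    seed: int = 0,
    return_mse: bool = False,
):
    """Grid-search the kernel width minimising MSE against Gaussian MI.

    For each replicate and correlation, a bivariate Gaussian sample of
    ``n_samples`` points is drawn once and copula-transformed; every
    candidate width is evaluated on the same draws.  Returns the width
    with minimal total MSE (optionally also the width -> MSE table).
    """
    if not width_grid or not rho_grid:
        raise ValidationError("width_grid and rho_grid must be non-empty")
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    datasets = []
    for rho in rho_grid:
        for _ in range(n_reps):
            x, y = _draw_bivariate(rng, rho, n_samples)
            datasets.append((copula_transform(x), copula_transform(y), gaussian_mi(rho)))
    mse = {}
    for h in width_grid:
        cfg = MIEstimatorConfig(kernel_width=h)
        err = [(mutual_information(u, v, cfg) - true_mi) ** 2 for u, v, true_mi in datasets]
        mse[h] = float(np.mean(err))
    best = min(mse, key=lambda h: (mse[h], h))
    logger.info("calibrated kernel width %.4f at n=%d (MSE %.3g)", best, n_samples, mse[best])
    return (best, mse) if return_mse else best


def calibrate_mi_threshold(
    n_samples: int,
    n_null_pairs: int,
    config: MIEstimatorConfig,
    seed: int = 0,
    tail_fraction: float = 0.5,
) -> NullFit:
    """Fit the null-MI log-survival line ln P(MI > I0) = alpha + beta*I0.

    Null MI values come from independent Gaussian profile pairs of the
    target sample size; the line is fitted by least squares over the upper
    ``tail_fraction`` of the empirical survival curve.
    """
    if n_null_pairs < 100:
        raise ValidationError("need at least 100 null pairs")
    rng = np.random.default_rng(seed)
    mis = np.empty(n_null_pairs)
    for i in range(n_null_pairs):
        x = copula_transform(rng.normal(size=n_samples))
        y = copula_transform(rng.normal(size=n_samples))
        mis[i] = mutual_information(x, y, config)
    mis.sort()
    if np.ptp(mis) == 0:
        raise ValidationError("degenerate null: all MI values identical")
    n = len(mis)
    surv = (n - np.arange(1, n + 1)) / n  # P(MI > mis[i]) strictly
    start = int(math.floor(n * (1.0 - tail_fraction)))
    sel = slice(start, n - 1)  # drop the final point with survival 0
    beta, alpha = np.polyfit(mis[sel], np.log(surv[sel]), 1)
    if beta >= 0:
        raise ValidationError("null survival fit is not decreasing")
    return NullFit(alpha=float(alpha), beta=float(beta), n_samples=n_samples)


def threshold_for_p(fit: NullFit, p: float) -> float:
    """Invert the null survival line: the MI threshold whose tail P-value is p."""
    if not (0 < p <= 1):
        raise ValidationError("p must lie in (0, 1]")
    return (math.log(p) - fit.alpha) / fit.beta


def apply_dpi(graph: nx.Graph, tolerance: float = 0.0) -> nx.Graph:
    """Data processing inequality pruning (in place, also returned).

    In every triangle, an edge is marked for removal when its weight is
    both the (weak) minimum of the triangle and <= (1 - tolerance) times
    the smaller of the other two weights; all marked edges are removed
    after every triangle has been examined.  Idempotent.
    """
    if not (0 <= tolerance < 1):
        raise ValidationError("dpi tolerance must lie in [0, 1)")
    marked = set()
    w = {frozenset(e): d["weight"] for *e, d in graph.edges(data=True)}
    for u, v in list(graph.edges):
        for t in sorted(set(graph[u]) & set(graph[v])):
            edges = [frozenset((u, v)), frozenset((u, t)), frozenset((v, t))]
            weights = [w[e] for e in edges]
            for e, we in zip(edges, weights):
                others = [x for ee, x in zip(edges, weights) if ee != e]
                if we <= min(others) and we <= (1.0 - tolerance) * min(others):
                    marked.add(e)
    graph.remove_edges_from(tuple(e) for e in marked)
    return graph


def build_network(
    delta,
    config: MIEstimatorConfig,
    i0: float,
    apply_dpi_flag: bool = True,
    dpi_tolerance: float = 0.0,
) -> nx.Graph:
    """All-pairs MI network thresholded at ``i0``, with optional DPI pruning."""
    if isinstance(delta, DeltaMatrix):
        genes = list(delta.matrix.index)
        X = delta.matrix.to_numpy(float)
    else:
        X = np.asarray(delta, float)
        genes = [f"g{i}" for i in range(X.shape[0])]
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 genes")
    U = copula_transform(X)
    M = all_pairs_mi(U, config.kernel_width)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for i, j in zip(*np.nonzero(np.triu(M >= i0, k=1))):
        g.add_edge(genes[i], genes[j], weight=float(M[i, j]))
    if apply_dpi_flag:
        apply_dpi(g, dpi_tolerance)
    g.graph.update(kernel_width=config.kernel_width, mi_threshold=i0,
                   dpi=bool(apply_dpi_flag), dpi_tolerance=dpi_tolerance)
    return g


def edge_support_pvalue(k: int, B: int, rate: float) -> float:
    """Upper-tail binomial P(X >= k) for X ~ Binomial(B, rate)."""
    return float(stats.binom.sf(k - 1, B, rate))


def bootstrap_consensus(
    delta: DeltaMatrix,
    config: MIEstimatorConfig,
    i0: float,
    B: int = 100,
    q_cutoff: float = 0.001,
    seed: int = 0,
) -> nx.Graph:
    """Bootstrap consensus network with a Bonferroni-corrected support test.

    ``B`` networks are built from subject-resampled (with replacement)
    deltas; an edge with support k is retained when its upper-tail
    binomial P-value under the mean-density null rate, multiplied by the
    number of candidate edges (support >= 1), is below ``q_cutoff``.
    Retained edges carry the full-data MI as weight and their support
    count.
    """
    if B < 2:
        raise ValidationError("bootstrap consensus needs B >= 2")
    rng = np.random.default_rng(seed)
    genes = list(delta.matrix.index)
    X = delta.matrix.to_numpy(float)
    G, n = X.shape
    n_pairs = G * (G - 1) // 2
    support: dict[tuple, int] = {}
    densities = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        U = copula_transform(X[:, idx])
        M = all_pairs_mi(U, config.kernel_width)
        ii, jj = np.nonzero(np.triu(M >= i0, k=1))
        densities.append(len(ii) / n_pairs)
        for i, j in zip(ii, jj):
            support[(genes[i], genes[j])] = support.get((genes[i], genes[j]), 0) + 1
    rate = float(np.mean(densities))
    m = len(support)
    consensus = nx.Graph()
    consensus.add_nodes_from(genes)
    if m:
        M_full = all_pairs_mi(copula_transform(X), config.kernel_width)
        gene_pos = {g: i for i, g in enumerate(genes)}
        for (a, b), k in sorted(support.items()):
            p = edge_support_pvalue(k, B, rate)
            if p * m < q_cutoff:
                consensus.add_edge(a, b, weight=float(M_full[gene_pos[a], gene_pos[b]]),
                                   support=k)
    consensus.graph.update(bootstrap_cycles=B, consensus_q=q_cutoff,
                           null_rate=rate, n_candidates=m, seed=seed)
    return consensus


def fit_power_law(degrees, method: str = "loglog_regression", xmin: int = 1) -> PowerLawFit:
    """Exponent of a power-law degree distribution P(k) ~ k^-gamma.

    ``loglog_regression`` regresses log frequency on log degree over
    logarithmically binned degrees >= xmin; ``mle`` maximises the discrete
    zeta likelihood.
    """
    k = np.asarray([d for d in degrees if d >= max(xmin, 1)], dtype=float)
    if len(k) < 10:
        raise ValidationError("need at least 10 degrees >= xmin")
    if np.ptp(k) == 0:
        raise ValidationError("degree distribution is degenerate (constant)")
    if method == "mle":
        logk_sum = float(np.log(k).sum())
        n = len(k)

        def nll(gamma):
            return gamma * logk_sum + n * math.log(float(special.zeta(gamma, xmin)))

        res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
        gamma = float(res.x)
    elif method == "loglog_regression":
        edges = [xmin * 2.0**j for j in range(0, 64)]
        edges = [e for e in edges if e <= k.max() * 2]
        hist, bin_edges = np.histogram(k, bins=edges)
        widths = np.diff(bin_edges)
        centers = np.sqrt(bin_edges[:-1] * bin_edges[1:])
        dens = hist / (widths * len(k))
        keep = dens > 0
        if keep.sum() < 3:
            raise ValidationError("too few occupied bins for a log-log regression")
        slope, _ = np.polyfit(np.log(centers[keep]), np.log(dens[keep]), 1)
        gamma = float(-slope)
    else:
        raise ValidationError(f"unknown method {method!r}")
    if gamma <= 0:
        raise ValidationError("fitted exponent is not positive")
    return PowerLawFit(gamma=gamma, fit_method=method, xmin=xmin)
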