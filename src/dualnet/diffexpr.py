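"""Per-gene linear modelling on baseline-corrected profiles.

Each gene's post-minus-pre difference is regressed on treatment arm, sex
and (standardised) age by ordinary least squares.  Residual variances are
then shrunk toward a pooled prior by empirical Bayes: the prior degrees of
freedom d0 and prior variance s0^2 are estimated by moment matching on the
log residual variances (digamma/trigamma inversion), the moderated
variance is the precision-weighted blend (d0*s0^2 + dg*sg^2)/(d0+dg), and
the moderated t statistic is referred to a t distribution on d0+dg degrees
of freedom.  Benjamini-Hochberg step-up q-values complete the table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .study import DeltaMatrix, ValidationError

logger = logging.getLogger(__name__)

_D0_CAP = 1e6  # effectively infinite prior df when moment matching degenerates


@dataclass
class LinearFits:
    """Per-gene OLS results for the treatment contrast."""

    genes: list
    coef: np.ndarray            # treated - placebo mean delta difference
    sigma: np.ndarray           # residual standard deviation per gene
    df_residual: int            # shared across genes
    se_scale: float             # sqrt([ (X'X)^-1 ]_tt ), unscaled SE of the contrast
    design_columns: tuple


def _design_matrix(subjects: pd.DataFrame, covariates) -> tuple[np.ndarray, tuple]:
    cols = [np.ones(len(subjects))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "treatment":
            cols.append((subjects["arm"] == "treated").to_numpy(float))
        elif cov == "sex":
            cols.append((subjects["sex"] == "F").to_numpy(float))
        elif cov == "age":
            age = subjects["age"].to_numpy(float)
            sd = age.std(ddof=0)
            if sd == 0:
                raise ValidationError("design is rank deficient: column 'age' is constant")
            cols.append((age - age.mean()) / sd)
        else:
            raise ValidationError(f"unknown covariate {cov!r}")
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns: constant or linearly dependent on the rest
        bad = [n for j, n in enumerate(names[1:], start=1)
               if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)]
        raise ValidationError(f"design is rank deficient: collinear columns {bad}")
    return X, tuple(names)


def fit_linear_model(delta: DeltaMatrix, covariates=("treatment", "sex", "age")) -> LinearFits:
    """OLS per gene on baseline-corrected values; treatment contrast + residual scale."""
    if "treatment" not in covariates:
        raise ValidationError("covariates must include 'treatment'")
    X, names = _design_matrix(delta.subjects.loc[delta.matrix.columns], covariates)
    n, p = X.shape
    if n < p + 1:
        raise ValidationError(f"{n} subjects cannot support {p} design columns")
    Y = delta.matrix.to_numpy(float).T  # subjects x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    t_idx = names.index("treatment")
    return LinearFits(
        genes=list(delta.matrix.index),
        coef=beta[t_idx],
        sigma=np.sqrt(sigma2),
        df_residual=df,
        se_scale=float(np.sqrt(xtx_inv[t_idx, t_idx])),
        design_columns=names,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(special.polygamma(1, x))
        step = (tri - y) / float(special.polygamma(2, x))
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * abs(x):
            return x_new
        x = x_new
    return x


def estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Returns ``(d0, s0sq)``; ``d0`` is capped at a large finite value when
    the observed spread of log variances is no larger than expected under
    a common variance.
    """
    sigma2 = np.asarray(sigma2, float)
    positive = sigma2[sigma2 > 0]
    if len(positive) < 2:
        raise ValidationError("need at least two positive residual variances")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        d0 = min(d0, _D0_CAP)
        s0sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        logger.warning("log-variance spread below sampling noise; prior df capped at %g", _D0_CAP)
        d0 = _D0_CAP
        s0sq = float(np.exp(e_mean))
    return d0, s0sq


def moderate_and_test(fits: LinearFits, d0_override: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test; returns the DE table sorted by P.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary t-test; very large values give equal-variance z-like tests).
    """
    if len(fits.genes) < 10 and d0_override is None:
        raise ValidationError("variance moderation needs at least 10 genes")
    sigma2 = fits.sigma**2
    df = fits.df_residual
    if np.all(sigma2 == 0):
        logger.warning("all residual variances are zero; falling back to ordinary t")
        d0, s0sq = 0.0, 0.0
    elif d0_override is not None:
        d0 = float(d0_override)
        s0sq = float(np.exp(np.mean(np.log(sigma2[sigma2 > 0])))) if d0 > 0 else 0.0
    else:
        d0, s0sq = estimate_prior(sigma2, df)

    if d0 > 0:
        s2_post = (d0 * s0sq + df * sigma2) / (d0 + df)
    else:
        s2_post = sigma2.copy()
    df_total = min(d0 + df, _D0_CAP)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.coef / (np.sqrt(s2_post) * fits.se_scale)
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no effect, no evidence
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": fits.genes,
            "coef": fits.coef,
            "residual_sd": fits.sigma,
            "df_residual": df,
            "moderated_t": t,
            "p_value": p,
            "q_value": q,
        }
    ).set_index("gene")
    table.attrs["d0"] = d0
    table.attrs["s0sq"] = s0sq
    return table.sort_values(["p_value", "gene"], kind="stable")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def correlate_profiles(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation of two profiles with a two-sided t-transform P-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def module_coherence(genes, delta: DeltaMatrix, method: str = "spearman") -> tuple[float, float]:
    """Mean and mean-absolute pairwise correlation over all gene pairs in a set."""
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in delta.matrix.index]
    if missing:
        raise ValidationError(f"genes missing from delta matrix: {missing}")
    if len(genes) < 2:
        raise ValidationError("need at least 2 genes")
    X = delta.matrix.loc[genes].to_numpy(float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    C = np.corrcoef(X)
    iu = np.triu_indices(len(genes), k=1)
    vals = C[iu]
    return float(vals.mean()), float(np.abs(vals).mean())
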