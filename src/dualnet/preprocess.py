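"""Background filtering via a sex-marker gene and within-subject baseline correction.

The background threshold is estimated from a gene expressed in one sex
only (an XIST-style marker): its median log2 intensity in the
non-expressing sex estimates the array background.  Genes whose intensity
never reaches that threshold in any sample are treated as unexpressed.
Baseline correction converts the paired design into one post-minus-pre
log2 difference profile per subject.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .study import DeltaMatrix, ExpressionStudy, ValidationError

logger = logging.getLogger(__name__)


def estimate_background_threshold(
    study: ExpressionStudy, marker_gene: str, negative_sex: str = "M"
) -> float:
    """Median log2 intensity of ``marker_gene`` across ``negative_sex`` samples."""
    if marker_gene not in study.matrix.index:
        raise ValidationError(f"marker gene {marker_gene!r} not in matrix")
    neg_samples = study.samples.index[study.samples["sex"] == negative_sex]
    if len(neg_samples) == 0:
        raise ValidationError(f"no samples with sex {negative_sex!r}")
    threshold = float(study.matrix.loc[marker_gene, neg_samples].median())
    logger.info(
        "background threshold %.4f from %d %s samples of marker %s",
        threshold, len(neg_samples), negative_sex, marker_gene,
    )
    return threshold


def filter_unexpressed(study: ExpressionStudy, threshold: float) -> ExpressionStudy:
    """Keep genes with at least one sample value >= ``threshold``.

    A gene is dropped only when *all* arrays fall below the threshold;
    ties at the threshold count as expressed.  Idempotent.
    """
    if np.isnan(threshold) or threshold == np.inf:
        raise ValidationError("threshold must be a real number or -inf")
    keep = (study.matrix >= threshold).any(axis=1)
    if not keep.any():
        logger.warning("filter_unexpressed removed every gene (threshold %.4f)", threshold)
    return ExpressionStudy(study.matrix.loc[keep], study.samples.copy())


def baseline_correct(study: ExpressionStudy) -> DeltaMatrix:
    """Post-minus-pre log2 difference per subject.

    Subjects lacking a complete pre/post pair are dropped with a warning
    (mirroring exclusion of technically failed arrays); zero complete
    pairs is an error.
    """
    cols = {}
    annot_rows = {}
    dropped = []
    for subject, group in study.samples.groupby("subject_id", sort=True):
        pre = group.index[group["timepoint"] == "pre"]
        post = group.index[group["timepoint"] == "post"]
        if len(pre) != 1 or len(post) != 1:
            dropped.append(subject)
            continue
        cols[subject] = study.matrix[post[0]].to_numpy() - study.matrix[pre[0]].to_numpy()
        row = group.loc[pre[0]]
        annot_rows[subject] = {"arm": row["arm"], "sex": row["sex"], "age": row["age"]}
    if dropped:
        logger.warning("dropping %d subject(s) without a complete pre/post pair: %s",
                       len(dropped), dropped)
    if not cols:
        raise ValidationError("no subject has a complete pre/post pair")
    matrix = pd.DataFrame(cols, index=study.matrix.index)
    subjects = pd.DataFrame.from_dict(annot_rows, orient="index")
    subjects.index.name = "subject_id"
    return DeltaMatrix(matrix, subjects)
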