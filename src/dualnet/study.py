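"""Core in-memory containers for a paired pre/post expression study.

An :class:`ExpressionStudy` holds a log2 expression matrix (genes x samples)
together with per-sample annotations; a :class:`DeltaMatrix` holds the
within-subject post-minus-pre log2 differences (one column per subject) that
every downstream stage operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("subject_id", "timepoint", "arm", "sex", "age")
TIMEPOINTS = ("pre", "post")
ARMS = ("treated", "placebo")
SEXES = ("M", "F")


class ValidationError(ValueError):
    """Raised when an input object violates its documented schema."""


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus per-sample annotations.

    Parameters
    ----------
    matrix
        genes x samples DataFrame of finite log2 intensities; the column
        index must equal ``samples.index`` (sample ids).
    samples
        One row per sample, indexed by sample id, with columns
        ``subject_id, timepoint, arm, sex, age``.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.matrix.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        if self.matrix.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample annotations missing columns: {missing}")
        if set(self.matrix.columns) != set(self.samples.index):
            raise ValidationError("matrix columns and sample annotations disagree")
        bad_tp = set(self.samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def subset_genes(self, genes) -> "ExpressionStudy":
        return ExpressionStudy(self.matrix.loc[list(genes)], self.samples.copy())


@dataclass
class DeltaMatrix:
    """Post-minus-pre log2 differences, one column per complete subject."""

    matrix: pd.DataFrame  # genes x subjects
    subjects: pd.DataFrame  # indexed by subject_id: arm, sex, age

    def __post_init__(self) -> None:
        if set(self.matrix.columns) != set(self.subjects.index):
            raise ValidationError("delta columns and subject annotations disagree")
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValidationError("delta matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[1]
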