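"""The in-memory container for a single-cohort miRNA expression matrix.

A cohort couples a features x samples abundance matrix with per-sample
case/control labels and a *scale* flag declaring the direction of the
measurement: on an ``expression`` scale larger values mean more abundant
(microarray intensities, normalized counts, log-expression), while on a
``ct`` scale larger values mean *less* abundant (qPCR cycle thresholds).
Absolute units are platform specific and are never compared across
cohorts; only within-sample orderings survive downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import ValidationError

COPD = "COPD"
HEALTHY = "healthy"
CLASSES = (COPD, HEALTHY)

SCALE_EXPRESSION = "expression"
SCALE_CT = "ct"
SCALES = (SCALE_EXPRESSION, SCALE_CT)


@dataclass
class ExpressionCohort:
    """A named miRNA abundance matrix with labels and a scale flag.

    Parameters
    ----------
    cohort_id
        Short identifier, e.g. a GEO accession.
    values
        ``features x samples`` float DataFrame; ``NaN`` marks a missing
        (undetected) measurement and is only resolved by
        :func:`mirpair.preprocess.impute_missing`.
    labels
        Per-sample class, indexed by sample ID, values in
        ``{"COPD", "healthy"}``.
    scale
        ``"expression"`` or ``"ct"``.
    """

    cohort_id: str
    values: pd.DataFrame
    labels: pd.Series
    scale: str = SCALE_EXPRESSION

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.labels = self.labels.astype(str)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(
                f"cohort {self.cohort_id!r}: unknown scale {self.scale!r}; "
                f"expected one of {SCALES}"
            )
        feats = self.values.index
        if feats.duplicated().any():
            dups = sorted(feats[feats.duplicated()].unique())
            raise ValidationError(
                f"cohort {self.cohort_id!r}: duplicate feature names {dups}"
            )
        samples = self.values.columns
        if samples.duplicated().any():
            dups = sorted(samples[samples.duplicated()].unique())
            raise ValidationError(
                f"cohort {self.cohort_id!r}: duplicate sample IDs {dups}"
            )
        missing_labels = [s for s in samples if s not in self.labels.index]
        if missing_labels:
            raise ValidationError(
                f"cohort {self.cohort_id!r}: no label for sample(s) "
                f"{missing_labels}"
            )
        bad = sorted(set(self.labels.loc[list(samples)]) - set(CLASSES))
        if bad:
            raise ValidationError(
                f"cohort {self.cohort_id!r}: unknown class label(s) {bad}; "
                f"expected {CLASSES}"
            )
        # align label order with the matrix and drop labels for absent samples
        self.labels = self.labels.loc[list(samples)]

    # -- convenience -----------------------------------------------------

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def class_counts(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def with_values(self, values: pd.DataFrame) -> "ExpressionCohort":
        """Copy of this cohort with a replaced value matrix."""
        return replace(self, values=values)

    def subset_features(self, features: list[str]) -> "ExpressionCohort":
        missing = [f for f in features if f not in self.values.index]
        if missing:
            raise ValidationError(
                f"cohort {self.cohort_id!r}: feature(s) not present: {missing}"
            )
        return replace(self, values=self.values.loc[list(features)])
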