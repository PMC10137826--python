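"""Detection-limit imputation and low-abundance filtering.

Platforms report undetected miRNAs either as empty cells or as values
pinned at the detection limit. Missing entries are replaced with the
cohort-wide sentinel for "undetected": the global minimum of the observed
matrix on an expression scale, or the global maximum on a Ct scale (a
high cycle threshold means few copies). Features stuck at the sentinel in
more than a threshold fraction of either class are then removed — they
carry no ordering information and only inject detection-limit noise into
the pair features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CLASSES, ExpressionCohort, SCALE_CT
from .errors import ValidationError

# observed values this close (relative) to the sentinel count as "at the
# detection limit"; survives serialization round-trips of imputed matrices
_SENTINEL_RTOL = 1e-12


@dataclass
class FilterReport:
    """Record of a low-abundance filtering pass."""

    removed: list[tuple[str, str, float]]  # (feature, group, proportion)
    threshold: float
    n_before: int
    n_after: int

    @property
    def removed_features(self) -> list[str]:
        seen: dict[str, None] = {}
        for name, _, _ in self.removed:
            seen.setdefault(name)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["feature", "group", "proportion"])


def detection_sentinel(cohort: ExpressionCohort) -> float:
    """The value that encodes "undetected" on this cohort's scale."""
    arr = cohort.values.to_numpy()
    if np.isnan(arr).all():
        raise ValidationError(
            f"cohort {cohort.cohort_id!r}: all values missing, no sentinel defined"
        )
    return float(np.nanmax(arr) if cohort.scale == SCALE_CT else np.nanmin(arr))


def impute_missing(cohort: ExpressionCohort) -> ExpressionCohort:
    """Replace missing entries with the cohort's detection sentinel.

    Expression-like cohorts use the global matrix minimum; Ct-like cohorts
    use the global maximum. No observed value is changed.
    """
    sentinel = detection_sentinel(cohort)
    values = cohort.values.fillna(sentinel)
    return cohort.with_values(values)


def filter_low_abundance(
    cohort: ExpressionCohort, threshold: float = 0.7
) -> tuple[ExpressionCohort, FilterReport]:
    """Drop features pinned at the detection limit in over ``threshold`` of a class.

    A feature is removed when, within the COPD group *or* within the
    healthy group, the fraction of samples whose value equals the
    cohort-wide sentinel is strictly greater than ``threshold``. Requires
    an imputed cohort (no missing entries) and both classes present.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if cohort.n_missing:
        raise ValidationError(
            f"cohort {cohort.cohort_id!r}: {cohort.n_missing} missing entries; "
            "run impute_missing first"
        )
    counts = cohort.class_counts()
    for cls in CLASSES:
        if counts[cls] == 0:
            raise ValidationError(
                f"cohort {cohort.cohort_id!r}: class {cls!r} has no samples"
            )
    sentinel = detection_sentinel(cohort)
    arr = cohort.values.to_numpy()
    at_limit = np.isclose(arr, sentinel, rtol=_SENTINEL_RTOL, atol=0.0)

    removed: list[tuple[str, str, float]] = []
    drop: set[str] = set()
    for cls in CLASSES:
        mask = (cohort.labels == cls).to_numpy()
        prop = at_limit[:, mask].mean(axis=1)
        for feat, p in zip(cohort.features, prop):
            if p > threshold:
                removed.append((feat, cls, float(p)))
                drop.add(feat)

    keep = [f for f in cohort.features if f not in drop]
    report = FilterReport(
        removed=removed,
        threshold=threshold,
        n_before=len(cohort.features),
        n_after=len(keep),
    )
    return cohort.subset_features(keep), report


def preprocess_cohort(
    cohort: ExpressionCohort, threshold: float = 0.7
) -> tuple[ExpressionCohort, FilterReport]:
    """Impute then filter — the order matters and is fixed."""
    return filter_low_abundance(impute_missing(cohort), threshold=threshold)
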