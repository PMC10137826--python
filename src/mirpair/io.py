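"""Reading, writing and cross-cohort harmonization of expression matrices.

File formats
------------
* Expression matrix: CSV/TSV, first column = miRNA names, header row =
  sample IDs, cells = floats; empty cells are missing values.
* Labels: two-column CSV/TSV ``sample_id,class`` with class in
  ``{COPD, healthy}``.
* Alias map: two-column CSV/TSV ``source_name,canonical_name`` used to
  re-annotate platform-specific probe names onto a common miRNA
  nomenclature (e.g. a miRBase release). The mapping content is
  user-supplied; many-to-one source->canonical is allowed in the file but
  collisions within one cohort are an error, never silently collapsed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import ExpressionCohort, SCALE_EXPRESSION
from .errors import ValidationError


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt", ".tab")) else ","


def read_labels(labels_path: str | Path) -> pd.Series:
    """Read a two-column sample_id -> class table into a Series."""
    df = pd.read_csv(labels_path, sep=_sep_for(labels_path), dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(
            f"labels file {labels_path}: expected two columns "
            "(sample_id, class)"
        )
    ids = df.iloc[:, 0].str.strip()
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"labels file {labels_path}: duplicate sample IDs {dups}")
    return pd.Series(df.iloc[:, 1].str.strip().to_numpy(), index=ids, name="class")


def read_cohort(
    matrix_path: str | Path,
    labels_path: str | Path,
    scale: str = SCALE_EXPRESSION,
    cohort_id: str | None = None,
) -> ExpressionCohort:
    """Read an expression matrix plus labels into a validated cohort.

    Empty cells parse as missing values; validation errors name the
    offending sample or feature.
    """
    values = pd.read_csv(matrix_path, sep=_sep_for(matrix_path), index_col=0)
    values.index = values.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()
    labels = read_labels(labels_path)
    if cohort_id is None:
        cohort_id = Path(matrix_path).stem
    return ExpressionCohort(cohort_id=cohort_id, values=values, labels=labels, scale=scale)


def write_cohort(
    cohort: ExpressionCohort,
    matrix_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    cohort.values.to_csv(matrix_path, sep=_sep_for(matrix_path))
    if labels_path is not None:
        cohort.labels.rename_axis("sample_id").to_csv(
            labels_path, sep=_sep_for(labels_path)
        )


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column source_name -> canonical_name table."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(
            f"alias map {path}: expected two columns (source, canonical)"
        )
    src = df.iloc[:, 0].str.strip()
    dst = df.iloc[:, 1].str.strip()
    mapping: dict[str, str] = {}
    for s, d in zip(src, dst):
        if s in mapping and mapping[s] != d:
            raise ValidationError(
                f"alias map {path}: source {s!r} maps to both "
                f"{mapping[s]!r} and {d!r}"
            )
        mapping[s] = d
    return mapping


def harmonize_names(cohort: ExpressionCohort, alias_map: dict[str, str]) -> ExpressionCohort:
    """Rename features to canonical names; values are never touched.

    Unmapped features pass through unchanged. Two source features mapping
    onto one canonical name is an error (merging probes is a scientific
    decision the caller must make explicitly).
    """
    renamed = [alias_map.get(f, f) for f in cohort.features]
    seen: dict[str, str] = {}
    collisions = []
    for old, new in zip(cohort.features, renamed):
        if new in seen:
            collisions.append((seen[new], old, new))
        seen[new] = old
    if collisions:
        msg = "; ".join(f"{a!r} and {b!r} -> {c!r}" for a, b, c in collisions)
        raise ValidationError(
            f"cohort {cohort.cohort_id!r}: alias map collapses features: {msg}"
        )
    values = cohort.values.copy()
    values.index = pd.Index(renamed, name=cohort.values.index.name)
    return cohort.with_values(values)


def intersect_features(cohorts: list[ExpressionCohort]) -> list[ExpressionCohort]:
    """Restrict every cohort to the lexicographically sorted common feature set.

    The shared order makes downstream pair enumeration identical across
    cohorts. Requires at least two cohorts and a non-empty intersection.
    """
    if len(cohorts) < 2:
        raise ValidationError("intersect_features needs at least two cohorts")
    common = set(cohorts[0].features)
    for c in cohorts[1:]:
        common &= set(c.features)
    if not common:
        ids = [c.cohort_id for c in cohorts]
        raise ValidationError(f"no features shared by cohorts {ids}")
    order = sorted(common)
    return [c.subset_features(order) for c in cohorts]
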