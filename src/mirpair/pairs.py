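"""The binary miRNA-pair transform.

Every unordered pair of miRNAs (A, B) becomes one binary feature per
sample: 0 when A is expressed *less* than B in that sample, 1 otherwise
(ties score 1). Because the score depends only on the within-sample
ordering of two measurements, it is invariant to any strictly increasing
transform of the whole matrix — which is exactly what differs between
microarray, RNA-seq and qPCR readouts of the same blood draw. Ct-scale
cohorts are compared with the inequality inverted (lower Ct = more
abundant), so a stored pair matrix always has expression-scale semantics.

Pair identifiers render as ``"A|B"``; canonical orientation is ``A < B``
lexicographically. Ties make the score orientation-dependent (both
orientations score 1), so the orientation is fixed once, at enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionCohort, SCALE_CT, SCALES
from .errors import ValidationError

PAIR_SEP = "|"


def pair_id(a: str, b: str) -> str:
    return f"{a}{PAIR_SEP}{b}"


def split_pair(pair: str) -> tuple[str, str]:
    parts = pair.split(PAIR_SEP)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValidationError(f"malformed pair identifier {pair!r}; expected 'A|B'")
    return parts[0], parts[1]


def pair_score(value_a: float, value_b: float, scale: str = "expression") -> int:
    """Score one pair in one sample: 0 iff A is less expressed than B, else 1.

    On a Ct scale the comparison inverts (higher Ct = less abundant), so
    the returned score always carries expression-scale semantics.
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}")
    if scale == SCALE_CT:
        return 0 if value_a > value_b else 1
    return 0 if value_a < value_b else 1


def enumerate_pairs(features: list[str]) -> list[str]:
    """All n(n-1)/2 unordered pairs in canonical (lexicographic) orientation.

    Enumeration order is deterministic: pairs of lexicographically sorted
    features, first member ascending then second ascending.
    """
    if len(features) < 2:
        raise ValidationError(f"need at least 2 features, got {len(features)}")
    if len(set(features)) != len(features):
        raise ValidationError("duplicate feature names in pair enumeration")
    ordered = sorted(features)
    return [pair_id(a, b) for a, b in combinations(ordered, 2)]


@dataclass
class PairMatrix:
    """Binary pair-feature x sample matrix with labels.

    ``scores`` rows are ``"A|B"`` pair IDs, columns are sample IDs, cells
    are 0/1 (uint8); ``labels`` is indexed by sample ID.
    """

    scores: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("pair scores must be 0 or 1")
        self.scores = self.scores.astype(np.uint8)
        if self.scores.index.duplicated().any():
            dups = sorted(self.scores.index[self.scores.index.duplicated()].unique())
            raise ValidationError(f"duplicate pair IDs {dups}")
        missing = [s for s in self.scores.columns if s not in self.labels.index]
        if missing:
            raise ValidationError(f"no label for sample(s) {missing}")
        self.labels = self.labels.loc[list(self.scores.columns)].astype(str)

    @property
    def pairs(self) -> list[str]:
        return list(self.scores.index)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    def subset_pairs(self, pairs: list[str]) -> "PairMatrix":
        missing = [p for p in pairs if p not in self.scores.index]
        if missing:
            raise ValidationError(f"pair(s) not in matrix: {missing}")
        return replace(self, scores=self.scores.loc[list(pairs)])

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, labels: pd.Series) -> "PairMatrix":
        scores = pd.read_csv(path, index_col=0)
        return cls(scores=scores, labels=labels)


def build_pair_matrix(
    cohort: ExpressionCohort, pairs: list[str] | str = "all"
) -> PairMatrix:
    """Transform an expression cohort into its binary pair matrix.

    ``pairs`` may be ``"all"`` (enumerate every canonical pair) or an
    explicit list of ``"A|B"`` identifiers, whose orientation is preserved
    (a trained model's schema may fix either orientation).
    """
    if cohort.n_missing:
        raise ValidationError(
            f"cohort {cohort.cohort_id!r} has missing values; preprocess first"
        )
    if isinstance(pairs, str):
        if pairs != "all":
            raise ValidationError(f"pairs must be 'all' or a list, got {pairs!r}")
        pair_list = enumerate_pairs(cohort.features)
    else:
        pair_list = list(pairs)

    values = cohort.values
    absent = sorted(
        {m for p in pair_list for m in split_pair(p) if m not in values.index}
    )
    if absent:
        raise ValidationError(
            f"cohort {cohort.cohort_id!r}: pair member(s) absent: {absent}"
        )

    a_names = [split_pair(p)[0] for p in pair_list]
    b_names = [split_pair(p)[1] for p in pair_list]
    va = values.loc[a_names].to_numpy()
    vb = values.loc[b_names].to_numpy()
    if cohort.scale == SCALE_CT:
        scores = (va <= vb).astype(np.uint8)  # lower Ct = more abundant
    else:
        scores = (va >= vb).astype(np.uint8)
    frame = pd.DataFrame(scores, index=pair_list, columns=values.columns)
    return PairMatrix(scores=frame, labels=cohort.labels)


def merge_cohorts(pair_matrices: list[PairMatrix]) -> PairMatrix:
    """Concatenate samples across pair matrices, restricted to shared pairs.

    Sample IDs must be disjoint across inputs; the pair set of the result
    is the intersection of the input pair sets, in canonical (sorted)
    order.
    """
    if len(pair_matrices) < 2:
        raise ValidationError("merge_cohorts needs at least two pair matrices")
    seen: set[str] = set()
    for pm in pair_matrices:
        overlap = seen & set(pm.samples)
        if overlap:
            raise ValidationError(
                f"duplicate sample IDs across cohorts: {sorted(overlap)}"
            )
        seen |= set(pm.samples)
    common = set(pair_matrices[0].pairs)
    for pm in pair_matrices[1:]:
        common &= set(pm.pairs)
    if not common:
        raise ValidationError("no pairs shared by all pair matrices")
    order = sorted(common)
    scores = pd.concat([pm.scores.loc[order] for pm in pair_matrices], axis=1)
    labels = pd.concat([pm.labels for pm in pair_matrices])
    return PairMatrix(scores=scores, labels=labels)


def drop_zero_variance(pair_matrix: PairMatrix) -> PairMatrix:
    """Optional post-step: drop pairs constant across all samples.

    Constant pairs (one miRNA always above the other in every sample)
    carry no information for any selector; dropping them is off by default
    throughout the pipeline.
    """
    arr = pair_matrix.scores.to_numpy()
    keep = arr.std(axis=1) > 0
    return replace(pair_matrix, scores=pair_matrix.scores.loc[keep])
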