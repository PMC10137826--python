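"""End-to-end driver: cohorts in, consensus pairs and a tuned model out.

Chains the stages in the fixed study order: per-cohort preprocessing
(impute, low-abundance filter), feature intersection, pair transform,
cross-cohort merge, four-selector consensus, stratified 70/30 split, and
grid-search training of the chosen classifier on the key pairs. Each
stage remains individually callable; this module only fixes the order
and carries the bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import ExpressionCohort
from .io import intersect_features
from .modeling import (
    DiagnosticMetrics,
    FittedClassifier,
    SplitPlan,
    evaluate,
    stratified_split,
    train_classifier,
)
from .pairs import PairMatrix, build_pair_matrix, merge_cohorts
from .preprocess import FilterReport, preprocess_cohort
from .selection import ConsensusSelection, select_key_pairs


@dataclass
class StudyResult:
    """Everything a pipeline run produces, stage by stage."""

    merged: PairMatrix
    consensus: ConsensusSelection
    split: SplitPlan | None = None
    model: FittedClassifier | None = None
    train_metrics: DiagnosticMetrics | None = None
    test_metrics: DiagnosticMetrics | None = None
    filter_reports: dict[str, FilterReport] = field(default_factory=dict)

    @property
    def key_pairs(self) -> list[str]:
        return list(self.consensus.key_pairs)


def merged_pair_matrix(
    cohorts: list[ExpressionCohort], low_abundance_threshold: float = 0.7
) -> tuple[PairMatrix, dict[str, FilterReport]]:
    """Preprocess, intersect, pair-transform and merge a list of cohorts."""
    reports: dict[str, FilterReport] = {}
    cleaned = []
    for cohort in cohorts:
        filtered, report = preprocess_cohort(cohort, threshold=low_abundance_threshold)
        reports[cohort.cohort_id] = report
        cleaned.append(filtered)
    aligned = intersect_features(cleaned)
    matrices = [build_pair_matrix(c, "all") for c in aligned]
    return merge_cohorts(matrices), reports


def run_study(
    cohorts: list[ExpressionCohort],
    algorithm: str = "lightgbm",
    auc_threshold: float = 0.7,
    top_k: int = 20,
    train_frac: float = 0.7,
    folds: int = 10,
    seed: int | None = None,
    fit_model: bool = True,
) -> StudyResult:
    """Run the whole pipeline on two or more cohorts.

    With ``fit_model`` false (or an empty consensus) the result stops
    after selection; otherwise the key-pair matrix is split 70/30 and
    the classifier is tuned by 10-fold CV on the training partition and
    evaluated once on the held-out partition.
    """
    merged, reports = merged_pair_matrix(cohorts)
    consensus = select_key_pairs(
        merged, auc_threshold=auc_threshold, top_k=top_k, seed=seed
    )
    result = StudyResult(merged=merged, consensus=consensus, filter_reports=reports)
    if not fit_model or not consensus.key_pairs:
        return result
    key_matrix = merged.subset_pairs(consensus.key_pairs)
    split = stratified_split(key_matrix.labels, train_frac=train_frac, seed=seed)
    model = train_classifier(
        key_matrix, split, algorithm=algorithm, folds=folds, seed=seed
    )
    result.split = split
    result.model = model
    result.train_metrics = evaluate(model, key_matrix, split.train_ids)
    result.test_metrics = evaluate(model, key_matrix, split.test_ids)
    return result
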