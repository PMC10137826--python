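"""Expression-level baseline: differential expression and single-miRNA ROC.

This is the conventional analysis the pair transform is measured
against. Differential expression works directly on each cohort's
abundance values (a Welch two-sample t-test per feature, with the fold
change taken as the case-minus-control mean difference on the working
scale, assumed log2-like), so its hit lists are *not* invariant to
per-platform monotone distortions — the contrast the pair features are
designed to remove.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import COPD, HEALTHY, ExpressionCohort, SCALE_CT
from .errors import ValidationError
from .modeling import AucCI, roc_auc_ci


@dataclass
class DEResult:
    """Per-feature differential-expression table and the thresholds used."""

    table: pd.DataFrame  # feature, logfc, p, adj_p, direction, flagged
    logfc_thresh: float
    p_thresh: float
    stringent: bool

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "feature"].tolist()


def _working_values(cohort: ExpressionCohort) -> pd.DataFrame:
    """Values with expression-scale direction (Ct cohorts are negated)."""
    return -cohort.values if cohort.scale == SCALE_CT else cohort.values


def differential_expression(
    cohort: ExpressionCohort,
    logfc_thresh: float = 1.5,
    p_thresh: float = 0.05,
    stringent: bool = True,
) -> DEResult:
    """Welch two-sample test per feature with a fold-change threshold.

    ``logfc`` is the COPD-minus-healthy mean difference on the working
    scale (log2-like by assumption). Stringent mode flags features
    passing both ``|logfc| > logfc_thresh`` and ``p < p_thresh``;
    relaxed mode uses the p threshold alone. Benjamini-Hochberg adjusted
    p-values are reported, but flagging uses the raw p-value. Features
    with zero variance in both groups and equal means get p = 1.
    """
    if cohort.n_missing:
        raise ValidationError("cohort has missing values; preprocess first")
    labels = cohort.labels
    mask_copd = (labels == COPD).to_numpy()
    mask_hc = (labels == HEALTHY).to_numpy()
    if mask_copd.sum() < 2 or mask_hc.sum() < 2:
        raise ValidationError("need at least 2 samples per class")
    values = _working_values(cohort).to_numpy()
    case = values[:, mask_copd]
    ctrl = values[:, mask_hc]
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # degenerate (zero-variance) features
    adj_p = multipletests(p, method="fdr_bh")[1]
    direction = np.where(logfc > 0, "up", "down")
    if stringent:
        flagged = (np.abs(logfc) > logfc_thresh) & (p < p_thresh)
    else:
        flagged = p < p_thresh
    table = pd.DataFrame(
        {
            "feature": cohort.features,
            "logfc": logfc,
            "p": p,
            "adj_p": adj_p,
            "direction": direction,
            "flagged": flagged,
        }
    )
    return DEResult(
        table=table, logfc_thresh=logfc_thresh, p_thresh=p_thresh, stringent=stringent
    )


def single_mirna_auc(cohort: ExpressionCohort, feature: str) -> AucCI:
    """Direction-corrected AUC of one miRNA's abundance, with DeLong CI.

    Ct-scale cohorts are negated first so the score always points in the
    expression direction; if the raw AUC falls below 0.5 the score is
    reversed before the interval is computed, so the reported AUC is
    orientation-free.
    """
    if feature not in cohort.values.index:
        raise ValidationError(f"feature {feature!r} not in cohort {cohort.cohort_id!r}")
    scores = _working_values(cohort).loc[feature].to_numpy()
    res = roc_auc_ci(scores, cohort.labels)
    if res.auc < 0.5:
        res = roc_auc_ci(-scores, cohort.labels)
    return res
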