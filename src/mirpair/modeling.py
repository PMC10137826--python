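"""Model training, tuning and diagnostic evaluation on pair features.

Seven classifier families are supported (k-NN, SVM, random forest, naive
Bayes, decision tree, XGBoost, LightGBM), each tuned by grid search with
stratified k-fold cross-validation on the training partition, selecting
the grid point with the best mean CV AUC; the held-out partition is
touched once. COPD is the positive class throughout and class assignment
uses a 0.5 probability threshold.

AUC confidence intervals use DeLong's variance estimate for the
tie-corrected rank AUC (a seeded bootstrap is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cohort import COPD, HEALTHY
from .errors import SchemaMismatchError, ValidationError
from .pairs import PairMatrix

ALGORITHMS = (
    "knn",
    "svm",
    "random_forest",
    "naive_bayes",
    "decision_tree",
    "xgboost",
    "lightgbm",
)

# Small default grids per algorithm; the tuning protocol (grid search over
# mean CV AUC) is fixed, the grids themselves are caller-overridable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [3, 5, 7]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [300], "max_depth": [None, 3]},
    "naive_bayes": {"alpha": [0.1, 1.0]},
    "decision_tree": {"max_depth": [2, 3, None]},
    "xgboost": {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
    "lightgbm": {"num_leaves": [3, 7], "min_child_samples": [5, 20]},
}


def _make_estimator(algorithm: str, seed: int | None):
    if algorithm == "knn":
        return KNeighborsClassifier()
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "naive_bayes":
        return BernoulliNB()
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            tree_method="hist",
        )
    if algorithm == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbose=-1
        )
    raise ValidationError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitPlan:
    """A stratified train/test partition of sample IDs."""

    train_ids: list[str]
    test_ids: list[str]
    train_frac: float
    seed: int | None
    train_counts: dict[str, int]
    test_counts: dict[str, int]


def stratified_split(
    labels: pd.Series, train_frac: float = 0.7, seed: int | None = None
) -> SplitPlan:
    """Per class, draw floor(train_frac * n_class) samples into training.

    The remainder forms the test partition; the draw is uniform without
    replacement and deterministic given ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValidationError(f"train_frac must be in (0,1), got {train_frac}")
    labels = labels.astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValidationError("both classes must be present for a stratified split")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in classes:
        ids = np.array(labels.index[labels == cls])
        n_train = math.floor(train_frac * len(ids))
        if n_train == 0 or n_train == len(ids):
            raise ValidationError(
                f"class {cls!r}: train_frac={train_frac} leaves an empty partition "
                f"(class size {len(ids)})"
            )
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return SplitPlan(
        train_ids=train_ids,
        test_ids=test_ids,
        train_frac=train_frac,
        seed=seed,
        train_counts={c: int((labels.loc[train_ids] == c).sum()) for c in classes},
        test_counts={c: int((labels.loc[test_ids] == c).sum()) for c in classes},
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class DiagnosticMetrics:
    """Confusion counts and the derived clinical rates (COPD = positive)."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auc: float | None = None
    auc_ci_low: float | None = None
    auc_ci_high: float | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)

    def __str__(self) -> str:  # 3-decimal display; full precision kept in fields
        parts = [
            f"tp={self.tp} fn={self.fn} tn={self.tn} fp={self.fp}",
            f"sensitivity={self.sensitivity:.3f}",
            f"specificity={self.specificity:.3f}",
            f"ppv={self.ppv:.3f}",
            f"npv={self.npv:.3f}",
            f"accuracy={self.accuracy:.3f}",
        ]
        if self.auc is not None:
            parts.append(
                f"auc={self.auc:.3f} (95% CI {self.auc_ci_low:.3f}-{self.auc_ci_high:.3f})"
            )
        return " ".join(parts)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> DiagnosticMetrics:
    """Exact diagnostic rates from a confusion table (no AUC)."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValidationError(f"count {name} must be >= 0, got {v}")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValidationError("empty confusion table")
    if tp + fn == 0:
        raise ValidationError("sensitivity undefined: no positive (COPD) samples")
    if tn + fp == 0:
        raise ValidationError("specificity undefined: no negative (healthy) samples")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return DiagnosticMetrics(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=ppv,
        npv=npv,
        accuracy=(tp + tn) / total,
    )


class AucCI(NamedTuple):
    auc: float
    ci_low: float
    ci_high: float


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def roc_auc_ci(
    scores: np.ndarray, labels: pd.Series | np.ndarray, level: float = 0.95
) -> AucCI:
    """Tie-corrected rank AUC with a DeLong confidence interval.

    Constant score vectors give AUC 0.5 with a zero-width (degenerate)
    interval. The interval is truncated to [0, 1].
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    y = (labels.to_numpy() == COPD).astype(int)
    if y.all() or not y.any():
        raise ValidationError("both classes must be present")
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    from scipy import stats

    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return AucCI(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
    )


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: pd.Series | np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> AucCI:
    """Percentile-bootstrap AUC interval (stratified resampling, seeded)."""
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    y = (labels.to_numpy() == COPD).astype(int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    rng = np.random.default_rng(seed)
    point = roc_auc_ci(s, labels).auc
    aucs = np.empty(n_boot)
    lab = pd.Series([COPD] * len(pos) + [HEALTHY] * len(neg))
    for i in range(n_boot):
        sp = rng.choice(pos, size=len(pos), replace=True)
        sn = rng.choice(neg, size=len(neg), replace=True)
        aucs[i] = roc_auc_ci(np.concatenate([sp, sn]), lab).auc
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
    return AucCI(auc=float(point), ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# training and evaluation


@dataclass
class FittedClassifier:
    """A tuned, trained model bound to an ordered pair-feature schema."""

    algorithm: str
    feature_schema: list[str]
    tuned_params: dict
    cv_summary: pd.DataFrame  # one row per fold: fold, auc
    model: object
    seed: int | None = None

    def _design(self, pair_matrix: PairMatrix, sample_ids: list[str] | None = None) -> pd.DataFrame:
        missing = [p for p in self.feature_schema if p not in pair_matrix.scores.index]
        if missing:
            raise SchemaMismatchError(f"pair matrix lacks schema pair(s): {missing}")
        X = pair_matrix.scores.loc[self.feature_schema]
        if sample_ids is not None:
            X = X[list(sample_ids)]
        return X.T.astype(float)

    def predict_proba(
        self, pair_matrix: PairMatrix, sample_ids: list[str] | None = None
    ) -> pd.Series:
        """P(COPD) per sample, in schema order."""
        X = self._design(pair_matrix, sample_ids)
        proba = self.model.predict_proba(X)
        pos_col = int(np.flatnonzero(np.asarray(self.model.classes_) == 1)[0])
        return pd.Series(proba[:, pos_col], index=X.index, name="p_copd")


def train_classifier(
    pair_matrix: PairMatrix,
    split: SplitPlan,
    algorithm: str,
    grid: dict[str, list] | None = None,
    folds: int = 10,
    seed: int | None = None,
) -> FittedClassifier:
    """Grid-search a classifier by mean CV AUC on the training partition.

    Stratified ``folds``-fold CV (shuffled, seeded) scores every grid
    point; ties go to the first-listed point. The winner is refit on the
    full training partition.
    """
    if algorithm not in ALGORITHMS:
        raise ValidationError(
            f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}"
        )
    grid = DEFAULT_GRIDS[algorithm] if grid is None else grid
    if not grid:
        raise ValidationError("parameter grid must be non-empty")
    X = pair_matrix.scores[list(split.train_ids)].T.astype(float)
    y = (pair_matrix.labels.loc[list(split.train_ids)] == COPD).astype(int).to_numpy()
    class_min = np.bincount(y, minlength=2).min()
    if class_min < folds:
        raise ValidationError(
            f"smallest training class has {class_min} samples < {folds} folds; "
            "use fewer folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(algorithm, seed),
        param_grid=grid,
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
        refit=True,
        error_score="raise",
    )
    search.fit(X, y)
    best = search.best_index_
    fold_scores = [
        float(search.cv_results_[f"split{i}_test_score"][best]) for i in range(folds)
    ]
    cv_summary = pd.DataFrame({"fold": range(folds), "auc": fold_scores})
    return FittedClassifier(
        algorithm=algorithm,
        feature_schema=list(pair_matrix.pairs),
        tuned_params=dict(search.best_params_),
        cv_summary=cv_summary,
        model=search.best_estimator_,
        seed=seed,
    )


def evaluate(
    model: FittedClassifier,
    pair_matrix: PairMatrix,
    sample_ids: list[str] | None = None,
    threshold: float = 0.5,
) -> DiagnosticMetrics:
    """Predict at the probability threshold and assemble all diagnostic metrics."""
    proba = model.predict_proba(pair_matrix, sample_ids)
    labels = pair_matrix.labels.loc[proba.index]
    y = (labels == COPD).to_numpy()
    pred = (proba.to_numpy() >= threshold)
    tp = int((pred & y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    fp = int((pred & ~y).sum())
    metrics = confusion_metrics(tp, fn, tn, fp)
    auc = roc_auc_ci(proba.to_numpy(), labels)
    metrics.auc, metrics.auc_ci_low, metrics.auc_ci_high = auc
    return metrics


# ---------------------------------------------------------------------------
# persistence


_ARCHIVE_VERSION = 1


def save_model(model: FittedClassifier, path: str | Path) -> None:
    """Persist a fitted classifier with its schema and tuning record."""
    payload = {
        "version": _ARCHIVE_VERSION,
        "algorithm": model.algorithm,
        "feature_schema": list(model.feature_schema),
        "tuned_params": dict(model.tuned_params),
        "cv_summary": model.cv_summary.to_dict(orient="list"),
        "seed": model.seed,
        "estimator": model.model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> FittedClassifier:
    payload = joblib.load(path)
    required = {"version", "algorithm", "feature_schema", "estimator"}
    if not isinstance(payload, dict) or not required <= set(payload):
        raise SchemaMismatchError(f"{path} is not a mirpair model archive")
    return FittedClassifier(
        algorithm=payload["algorithm"],
        feature_schema=list(payload["feature_schema"]),
        tuned_params=dict(payload.get("tuned_params", {})),
        cv_summary=pd.DataFrame(payload.get("cv_summary", {})),
        model=payload["estimator"],
        seed=payload.get("seed"),
    )
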