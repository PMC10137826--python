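"""Four feature selectors over binary pair features, and their consensus.

The selectors are deliberately heterogeneous — a univariate ROC filter,
two information-theoretic rankers (information gain and MRMR) and an
all-relevant wrapper (Boruta) — and the key pairs are the intersection of
the four selected sets. Agreement across unrelated selection principles
is the guard against any single method's bias.

All entropies and mutual informations are in bits. Ranking ties are
broken by canonical pair-ID order so every selector is deterministic
given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .cohort import COPD
from .errors import ValidationError
from .pairs import PairMatrix

METHODS = ("auc", "infogain", "mrmr", "boruta")


@dataclass
class SelectionResult:
    """Ranked and selected pairs from one selection method."""

    method: str
    ranked: pd.DataFrame  # ordered; columns at least (pair, score)
    selected: list[str]
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.ranked.copy()
        out["selected"] = out["pair"].isin(set(self.selected))
        out.insert(0, "method", self.method)
        return out


@dataclass
class ConsensusSelection:
    """The four per-method results and their intersection (the key pairs)."""

    per_method: dict[str, SelectionResult]
    key_pairs: list[str]
    overlap_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "key_pairs": list(self.key_pairs),
            "methods": {
                m: {"n_selected": len(r.selected), "params": dict(r.params)}
                for m, r in self.per_method.items()
            },
        }


# ---------------------------------------------------------------------------
# shared helpers


def _binary_labels(labels: pd.Series) -> np.ndarray:
    y = (labels.to_numpy() == COPD).astype(np.uint8)
    if y.all() or not y.any():
        raise ValidationError("both classes must be present in the labels")
    return y


def _entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits along the last axis; 0 log 0 := 0."""
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def _mi_bits(n11: np.ndarray, n10: np.ndarray, n01: np.ndarray, n00: np.ndarray) -> np.ndarray:
    """Mutual information in bits from 2x2 contingency counts (vectorized)."""
    n = n11 + n10 + n01 + n00
    joint = np.stack([n11, n10, n01, n00], axis=-1) / n[..., None]
    px1 = (n11 + n10) / n
    pz1 = (n11 + n01) / n
    hx = _entropy(np.stack([px1, 1 - px1], axis=-1))
    hz = _entropy(np.stack([pz1, 1 - pz1], axis=-1))
    hxz = _entropy(joint)
    return np.maximum(hx + hz - hxz, 0.0)


def _mi_with_label(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """I(X_j; Y) in bits for each row of binary matrix X against binary y."""
    Xf = X.astype(float)
    n11 = Xf @ y
    n10 = Xf @ (1 - y)
    n01 = (1 - Xf) @ y
    n00 = (1 - Xf) @ (1 - y)
    return _mi_bits(n11, n10, n01, n00)


# ---------------------------------------------------------------------------
# ROC filter


class BinaryAuc(NamedTuple):
    auc: float
    corrected: float


def binary_feature_auc(scores: np.ndarray, labels: pd.Series | np.ndarray) -> BinaryAuc:
    """AUC of one 0/1 feature as predictor of COPD.

    The tie-aware rank AUC of a binary predictor reduces to
    ``(TPR + TNR) / 2`` with TPR = P(score=1 | COPD) and
    TNR = P(score=0 | healthy). Returns the raw AUC together with the
    direction-corrected ``max(AUC, 1 - AUC)`` used for filtering, so an
    informative pair is never lost to its arbitrary orientation.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    y = _binary_labels(labels)
    s = np.asarray(scores, dtype=float)
    tpr = s[y == 1].mean()
    tnr = 1.0 - s[y == 0].mean()
    auc = (tpr + tnr) / 2.0
    return BinaryAuc(auc=float(auc), corrected=float(max(auc, 1.0 - auc)))


def auc_filter(pair_matrix: PairMatrix, threshold: float = 0.7) -> SelectionResult:
    """Select pairs whose direction-corrected AUC strictly exceeds ``threshold``."""
    y = _binary_labels(pair_matrix.labels)
    X = pair_matrix.scores.to_numpy().astype(float)
    tpr = X[:, y == 1].mean(axis=1)
    tnr = 1.0 - X[:, y == 0].mean(axis=1)
    auc = (tpr + tnr) / 2.0
    corrected = np.maximum(auc, 1.0 - auc)
    ranked = (
        pd.DataFrame(
            {"pair": pair_matrix.pairs, "score": corrected, "raw_auc": auc}
        )
        .sort_values(["score", "pair"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    selected = ranked.loc[ranked["score"] > threshold, "pair"].tolist()
    return SelectionResult(
        method="auc", ranked=ranked, selected=selected, params={"threshold": threshold}
    )


# ---------------------------------------------------------------------------
# information gain


def information_gain_rank(pair_matrix: PairMatrix, k: int = 20) -> SelectionResult:
    """Rank pairs by information gain IG(Y; X) = H(Y) - H(Y|X); keep the top k."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    y = _binary_labels(pair_matrix.labels)
    X = pair_matrix.scores.to_numpy()
    ig = _mi_with_label(X, y)  # IG(Y;X) == I(X;Y)
    ranked = (
        pd.DataFrame({"pair": pair_matrix.pairs, "score": ig})
        .sort_values(["score", "pair"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    selected = ranked["pair"].head(k).tolist()
    return SelectionResult(
        method="infogain", ranked=ranked, selected=selected, params={"k": k}
    )


# ---------------------------------------------------------------------------
# MRMR (MID variant)


def mrmr_rank(pair_matrix: PairMatrix, k: int = 20) -> SelectionResult:
    """Greedy minimum-redundancy maximum-relevance ranking (MID scheme).

    The first pick maximizes relevance I(X; Y); each later pick maximizes
    ``I(X; Y) - mean_{Z in S} I(X; Z)`` over unselected features, where S
    is the already-selected set. Returns the first k picks in selection
    order with the criterion value at the step each was picked.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    n_pairs = len(pair_matrix.pairs)
    if k > n_pairs:
        raise ValidationError(f"k={k} exceeds the number of pairs ({n_pairs})")
    y = _binary_labels(pair_matrix.labels)
    X = pair_matrix.scores.to_numpy()
    pairs = np.array(pair_matrix.pairs)
    relevance = _mi_with_label(X, y)

    # lexicographically smallest pair wins criterion ties
    lex_order = np.argsort(pairs, kind="stable")
    lex_rank = np.empty(n_pairs, dtype=int)
    lex_rank[lex_order] = np.arange(n_pairs)

    def argmax_tiebreak(crit: np.ndarray, candidates: np.ndarray) -> int:
        best = crit[candidates].max()
        tied = candidates[np.isclose(crit[candidates], best, rtol=0, atol=1e-12)]
        return int(tied[np.argmin(lex_rank[tied])])

    selected_idx: list[int] = []
    criterion_at_pick: list[float] = []
    redundancy_sum = np.zeros(n_pairs)
    remaining = np.arange(n_pairs)

    first = argmax_tiebreak(relevance, remaining)
    selected_idx.append(first)
    criterion_at_pick.append(float(relevance[first]))
    remaining = remaining[remaining != first]

    Xf = X.astype(float)
    for _ in range(1, k):
        z = X[selected_idx[-1]].astype(np.uint8)
        n11 = Xf @ z
        n10 = Xf @ (1 - z)
        n01 = (1 - Xf) @ z
        n00 = (1 - Xf) @ (1 - z)
        redundancy_sum += _mi_bits(n11, n10, n01, n00)
        crit = relevance - redundancy_sum / len(selected_idx)
        pick = argmax_tiebreak(crit, remaining)
        selected_idx.append(pick)
        criterion_at_pick.append(float(crit[pick]))
        remaining = remaining[remaining != pick]

    ranked = pd.DataFrame(
        {
            "pair": pairs[selected_idx],
            "score": criterion_at_pick,
            "relevance": relevance[selected_idx],
        }
    )
    return SelectionResult(
        method="mrmr", ranked=ranked, selected=list(pairs[selected_idx]), params={"k": k}
    )


# ---------------------------------------------------------------------------
# Boruta


def boruta_select(
    pair_matrix: PairMatrix,
    max_iter: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    n_estimators: int = 50,
    min_shadow_features: int = 200,
) -> SelectionResult:
    """All-relevant selection by shadow-feature comparison (Boruta).

    Each iteration appends a sample-shuffled shadow copy of every
    feature, fits a random forest, and records a "hit" for each real
    feature whose impurity importance exceeds the maximum shadow
    importance. The shadow pool is padded with additional independent
    permutations up to ``min_shadow_features`` columns: the hit bar is a
    *maximum* over the pool, so a small pool would place it at too low a
    null quantile and let chance-correlated features pass consistently;
    a floor keeps the bar's null quantile comparably high across problem
    sizes. After every iteration a two-sided binomial test (null:
    hit probability 1/2) with Bonferroni correction over all features
    either confirms (hit rate significantly above 1/2) or rejects
    (significantly below) each feature; rejected features leave the
    forest. Confirmed features are ``selected``; features still tentative
    at ``max_iter`` are reported in ``params`` but never selected.

    Features whose hit count provably cannot reach either decision
    threshold within the remaining iterations are finalized as tentative
    early — an exact shortcut that leaves the confirmed/rejected outcome
    unchanged.
    """
    y = _binary_labels(pair_matrix.labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 5:
        raise ValidationError(
            f"boruta needs >= 5 samples per class, got {counts.tolist()}"
        )
    X_all = pair_matrix.scores.to_numpy().T.astype(np.float32)  # samples x pairs
    pairs = np.array(pair_matrix.pairs)
    n_features = len(pairs)
    if X_all.std(axis=0).max() == 0:
        raise ValidationError("all pair features are constant; nothing to select")

    rng = np.random.default_rng(seed)
    hits = np.zeros(n_features, dtype=int)
    trials = np.zeros(n_features, dtype=int)
    status = np.zeros(n_features, dtype=int)  # 0 tentative, 1 confirmed, -1 rejected
    importance_sum = np.zeros(n_features)

    n_tests = 2.0 * n_features  # Bonferroni over features and both test sides
    for it in range(max_iter):
        undecided = status == 0
        if not undecided.any():
            break
        active = undecided | (status == 1)  # confirmed stay in the forest
        idx = np.flatnonzero(active)
        Xa = X_all[:, idx]
        # shadows mirror ALL original features (a constant-size null pool),
        # padded with extra permutations up to the floor
        copies = max(1, -(-min_shadow_features // n_features))
        shadows = np.hstack([rng.permuted(X_all, axis=0) for _ in range(copies)])
        Z = np.hstack([Xa, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        try:
            rf.fit(Z, y)
        except Exception as exc:  # pragma: no cover
            raise ValidationError(f"boruta importance estimator failed: {exc}") from exc
        imp = rf.feature_importances_
        max_shadow = imp[len(idx):].max()
        hit = imp[: len(idx)] > max_shadow
        upd = idx[undecided[idx]]
        hits[upd] += hit[undecided[idx]]
        trials[upd] += 1
        importance_sum[idx] += imp[: len(idx)]

        # binomial decision for still-tentative features
        t = trials[upd]
        h = hits[upd]
        p_hi = stats.binom.sf(h - 1, t, 0.5)  # P(hits >= h)
        p_lo = stats.binom.cdf(h, t, 0.5)  # P(hits <= h)
        confirm = p_hi * n_tests < alpha
        reject = p_lo * n_tests < alpha
        status[upd[confirm]] = 1
        status[upd[reject & ~confirm]] = -1

        # exact early exit: stop when no still-undecided feature could
        # reach either decision even with all hits (or all misses) in the
        # remaining iterations
        left = max_iter - (it + 1)
        und = np.flatnonzero(status == 0)
        if left > 0 and und.size:
            t_f = trials[und] + left
            best_confirm = stats.binom.sf(hits[und] + left - 1, t_f, 0.5)
            best_reject = stats.binom.cdf(hits[und], t_f, 0.5)
            if not ((best_confirm * n_tests < alpha) | (best_reject * n_tests < alpha)).any():
                break

    decision = np.where(status == 1, "confirmed", np.where(status == -1, "rejected", "tentative"))
    mean_imp = np.divide(
        importance_sum, np.maximum(trials, 1), out=np.zeros_like(importance_sum), where=trials > 0
    )
    hit_rate = np.divide(hits, np.maximum(trials, 1))
    ranked = (
        pd.DataFrame(
            {
                "pair": pairs,
                "score": hit_rate,
                "mean_importance": mean_imp,
                "decision": decision,
                "trials": trials,
            }
        )
        .sort_values(["score", "pair"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    selected = sorted(pairs[status == 1])
    tentative = sorted(pairs[status == 0])
    return SelectionResult(
        method="boruta",
        ranked=ranked,
        selected=selected,
        params={
            "max_iter": max_iter,
            "alpha": alpha,
            "seed": seed,
            "n_estimators": n_estimators,
            "tentative": tentative,
            "n_rejected": int((status == -1).sum()),
        },
    )


# ---------------------------------------------------------------------------
# consensus


def intersect_selections(results: list[SelectionResult]) -> ConsensusSelection:
    """Key pairs = intersection of the four methods' selected sets."""
    by_method = {r.method: r for r in results}
    missing = [m for m in METHODS if m not in by_method]
    if missing or len(results) != len(METHODS):
        raise ValidationError(
            f"need exactly one result per method {METHODS}; missing {missing}"
        )
    sets = {m: set(by_method[m].selected) for m in METHODS}
    key = set.intersection(*sets.values())
    overlap = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(METHODS)
        for b in METHODS[i + 1:]
    }
    return ConsensusSelection(
        per_method=by_method, key_pairs=sorted(key), overlap_counts=overlap
    )


def select_key_pairs(
    pair_matrix: PairMatrix,
    auc_threshold: float = 0.7,
    top_k: int = 20,
    boruta_max_iter: int = 100,
    boruta_alpha: float = 0.05,
    seed: int | None = None,
) -> ConsensusSelection:
    """Run all four selectors with their defaults and intersect the results."""
    results = [
        auc_filter(pair_matrix, threshold=auc_threshold),
        information_gain_rank(pair_matrix, k=top_k),
        mrmr_rank(pair_matrix, k=min(top_k, len(pair_matrix.pairs))),
        boruta_select(
            pair_matrix, max_iter=boruta_max_iter, alpha=boruta_alpha, seed=seed
        ),
    ]
    return intersect_selections(results)
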