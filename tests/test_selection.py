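import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpair import (
    COPD,
    HEALTHY,
    ValidationError,
    auc_filter,
    binary_feature_auc,
    boruta_select,
    information_gain_rank,
    intersect_selections,
    mrmr_rank,
)
from mirpair.selection import SelectionResult

from conftest import make_pair_matrix

# ---------------------------------------------------------------------------
# independent oracles (naive, loop-based; used only to check the package)


def mw_auc(scores, labels):
    """AUC via scipy's Mann-Whitney U (tie-corrected), U / (n1 * n0)."""
    s = np.asarray(scores, float)
    y = np.asarray([1 if l == COPD else 0 for l in labels])
    pos, neg = s[y == 1], s[y == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


def entropy_bits(counts):
    n = sum(counts)
    return -sum((c / n) * math.log2(c / n) for c in counts if c)


def mi_bits(x, z):
    """I(X;Z) in bits by direct joint-count arithmetic."""
    x = np.asarray(x)
    z = np.asarray(z)
    n = len(x)
    hx = entropy_bits([(x == v).sum() for v in (0, 1)])
    hz = entropy_bits([(z == v).sum() for v in (0, 1)])
    hxz = entropy_bits([((x == a) & (z == b)).sum() for a in (0, 1) for b in (0, 1)])
    return hx + hz - hxz


# ---------------------------------------------------------------------------


class TestBinaryFeatureAuc:
    def test_perfect_separation(self):
        labels = [COPD] * 3 + [HEALTHY] * 3
        res = binary_feature_auc([1, 1, 1, 0, 0, 0], pd.Series(labels))
        assert res.auc == 1.0

    def test_independent_feature_is_half(self):
        labels = [COPD] * 4 + [HEALTHY] * 4
        res = binary_feature_auc([1, 1, 0, 0, 1, 1, 0, 0], pd.Series(labels))
        assert res.auc == 0.5

    def test_six_sample_toy_matches_mann_whitney(self):
        scores = [1, 1, 0, 0, 0, 1]
        labels = [COPD] * 3 + [HEALTHY] * 3
        res = binary_feature_auc(scores, pd.Series(labels))
        assert res.auc == pytest.approx(2 / 3)
        assert res.auc == pytest.approx(mw_auc(scores, labels))

    def test_matches_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n0 = rng.integers(2, 16, size=2)
            labels = [COPD] * n1 + [HEALTHY] * n0
            scores = rng.integers(0, 2, size=n1 + n0)
            if scores[:n1].std() == 0 and scores[n1:].std() == 0 and scores.std() == 0:
                continue
            res = binary_feature_auc(scores, pd.Series(labels))
            assert res.auc == pytest.approx(mw_auc(scores, labels), abs=1e-12)
            assert res.corrected == pytest.approx(max(res.auc, 1 - res.auc))

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError):
            binary_feature_auc([0, 1], pd.Series([COPD, COPD]))


class TestAucFilter:
    def test_planted_perfect_pair_selected(self):
        rng = np.random.default_rng(1)
        n = 120
        labels = [COPD] * 60 + [HEALTHY] * 60
        scores = rng.integers(0, 2, size=(51, n))
        scores[0] = [1] * 60 + [0] * 60
        pm = make_pair_matrix(scores, labels=labels)
        res = auc_filter(pm, threshold=0.7)
        assert pm.pairs[0] in res.selected
        assert res.ranked.iloc[0]["pair"] == pm.pairs[0]

    def test_threshold_is_strict(self):
        # a pair at exactly AUC 1.0 passes threshold 0.7 but not 1.0
        pm = make_pair_matrix(
            [[1, 1, 0, 0], [1, 0, 1, 0]], labels=[COPD, COPD, HEALTHY, HEALTHY]
        )
        assert auc_filter(pm, threshold=1.0).selected == []
        assert pm.pairs[0] in auc_filter(pm, threshold=0.7).selected

    def test_direction_corrected_selection(self):
        # reversed-orientation perfect pair (AUC 0) must still be selected
        pm = make_pair_matrix(
            [[0, 0, 1, 1], [1, 0, 1, 0]], labels=[COPD, COPD, HEALTHY, HEALTHY]
        )
        res = auc_filter(pm)
        assert pm.pairs[0] in res.selected
        row = res.ranked.set_index("pair").loc[pm.pairs[0]]
        assert row["raw_auc"] == 0.0 and row["score"] == 1.0

    def test_null_selection_count_small(self):
        # label permutation destroys selection: expected count < 1 at n=120
        rng = np.random.default_rng(2)
        labels = [COPD] * 60 + [HEALTHY] * 60
        total = 0
        n_rep = 20
        for _ in range(n_rep):
            pm = make_pair_matrix(rng.integers(0, 2, size=(50, 120)), labels=labels)
            total += len(auc_filter(pm).selected)
        assert total / n_rep < 1


class TestInformationGain:
    def test_perfect_balanced_pair_is_one_bit(self):
        pm = make_pair_matrix([[1, 1, 0, 0]], labels=[COPD, COPD, HEALTHY, HEALTHY])
        res = information_gain_rank(pm, k=1)
        assert res.ranked.iloc[0]["score"] == pytest.approx(1.0)

    def test_independent_pair_is_zero(self):
        pm = make_pair_matrix([[1, 0, 1, 0]], labels=[COPD, COPD, HEALTHY, HEALTHY])
        res = information_gain_rank(pm, k=1)
        assert res.ranked.iloc[0]["score"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_entropy_arithmetic(self):
        # COPD: 8 ones, 2 zeros; healthy: 3 ones, 7 zeros
        x = [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7
        y = [COPD] * 10 + [HEALTHY] * 10
        hy = entropy_bits([10, 10])
        p1 = 11 / 20
        hy_given = p1 * entropy_bits([8, 3]) + (1 - p1) * entropy_bits([2, 7])
        expected = hy - hy_given
        pm = make_pair_matrix([x], labels=y)
        res = information_gain_rank(pm, k=1)
        assert res.ranked.iloc[0]["score"] == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_and_bounded_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n1, n0 = rng.integers(3, 15, size=2)
            labels = [COPD] * n1 + [HEALTHY] * n0
            x = rng.integers(0, 2, size=(6, n1 + n0))
            pm = make_pair_matrix(x, labels=labels)
            res = information_gain_rank(pm, k=6)
            hy = entropy_bits([n1, n0])
            for _, row in res.ranked.iterrows():
                xi = pm.scores.loc[row["pair"]].to_numpy()
                hx = entropy_bits([(xi == 0).sum(), (xi == 1).sum()])
                assert -1e-12 <= row["score"] <= min(hx, hy) + 1e-9
                assert row["score"] == pytest.approx(
                    mi_bits(xi, [1 if l == COPD else 0 for l in labels]), abs=1e-9
                )


class TestMrmr:
    def test_duplicate_of_best_pair_is_penalized(self):
        rng = np.random.default_rng(4)
        labels = [COPD] * 20 + [HEALTHY] * 20
        best = np.array([1] * 18 + [0] * 2 + [0] * 18 + [1] * 2)
        weaker = (rng.random(40) < 0.3).astype(int)
        weaker[:20] |= rng.random(20) < 0.4  # mildly informative
        pm = make_pair_matrix(
            [best, best.copy(), weaker],
            pairs=["a|b", "c|d", "e|f"],
            labels=labels,
        )
        res = mrmr_rank(pm, k=2)
        assert res.selected[0] in {"a|b", "c|d"}
        assert res.selected[1] == "e|f"

    def test_k1_agrees_with_information_gain_top1(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            labels = [COPD] * 10 + [HEALTHY] * 10
            pm = make_pair_matrix(rng.integers(0, 2, size=(8, 20)), labels=labels)
            assert mrmr_rank(pm, k=1).selected[0] == information_gain_rank(pm, k=1).selected[0]

    def test_greedy_trace_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(12, 30))
            n1 = n // 2
            labels = [COPD] * n1 + [HEALTHY] * (n - n1)
            y = np.array([1] * n1 + [0] * (n - n1))
            X = rng.integers(0, 2, size=(6, n))
            pm = make_pair_matrix(X, labels=labels)
            pairs = pm.pairs
            res = mrmr_rank(pm, k=4)

            # independent greedy: exhaustive criterion evaluation per step
            selected = []
            remaining = list(range(6))
            for _step in range(4):
                crits = []
                for i in remaining:
                    rel = mi_bits(X[i], y)
                    red = (
                        np.mean([mi_bits(X[i], X[j]) for j in selected])
                        if selected
                        else 0.0
                    )
                    crits.append((rel - red, pairs[i]))
                # max criterion, ties to lexicographically smallest pair
                best_val = max(c for c, _ in crits)
                cand = sorted(p for c, p in crits if abs(c - best_val) <= 1e-12)
                pick = cand[0]
                selected.append(pairs.index(pick))
                remaining.remove(selected[-1])
            assert res.selected == [pairs[i] for i in selected]

    def test_k_exceeding_pairs_is_error(self):
        pm = make_pair_matrix([[1, 0, 1, 0]], labels=[COPD, COPD, HEALTHY, HEALTHY])
        with pytest.raises(ValidationError):
            mrmr_rank(pm, k=2)


class TestBoruta:
    def _planted(self, seed, n=100, n_null=20):
        rng = np.random.default_rng(seed)
        labels = [COPD] * (n // 2) + [HEALTHY] * (n // 2)
        X = rng.integers(0, 2, size=(n_null + 1, n))
        X[0] = [1] * (n // 2) + [0] * (n // 2)  # label equals this pair's score
        return make_pair_matrix(X, labels=labels), X

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_perfect_pair_confirmed_nulls_never(self, seed):
        pm, _ = self._planted(seed)
        res = boruta_select(pm, seed=seed)
        assert pm.pairs[0] in res.selected
        # null pairs are rejected or tentative, never confirmed
        assert set(res.selected) == {pm.pairs[0]}

    def test_max_iter_one_leaves_all_tentative(self):
        pm, _ = self._planted(9)
        res = boruta_select(pm, max_iter=1, seed=0)
        assert res.selected == []
        assert set(res.params["tentative"]) == set(pm.pairs)

    def test_too_few_samples_per_class_is_error(self):
        pm = make_pair_matrix(
            [[1, 0, 1, 0]], labels=[COPD, COPD, HEALTHY, HEALTHY]
        )
        with pytest.raises(ValidationError, match="5 samples"):
            boruta_select(pm, seed=0)

    def test_constant_feature_set_is_error(self):
        labels = [COPD] * 5 + [HEALTHY] * 5
        pm = make_pair_matrix(np.ones((3, 10), dtype=int), labels=labels)
        with pytest.raises(ValidationError, match="constant"):
            boruta_select(pm, seed=0)

    def test_deterministic_given_seed(self):
        pm, _ = self._planted(12)
        r1 = boruta_select(pm, seed=5)
        r2 = boruta_select(pm, seed=5)
        assert r1.selected == r2.selected
        assert r1.ranked.equals(r2.ranked)


class TestIntersectSelections:
    def _result(self, method, selected):
        ranked = pd.DataFrame({"pair": selected, "score": 1.0})
        return SelectionResult(method=method, ranked=ranked, selected=list(selected))

    def test_intersection_example(self):
        res = intersect_selections(
            [
                self._result("auc", ["a|b", "c|d"]),
                self._result("infogain", ["a|b"]),
                self._result("mrmr", ["a|b", "e|f"]),
                self._result("boruta", ["a|b", "c|d"]),
            ]
        )
        assert res.key_pairs == ["a|b"]
        assert res.overlap_counts[("auc", "boruta")] == 2

    def test_identical_sets_give_that_set(self):
        sel = ["a|b", "c|d"]
        res = intersect_selections([self._result(m, sel) for m in
                                    ("auc", "infogain", "mrmr", "boruta")])
        assert res.key_pairs == sel

    def test_order_invariant(self):
        results = [
            self._result("mrmr", ["a|b", "e|f"]),
            self._result("auc", ["a|b", "c|d"]),
            self._result("boruta", ["a|b"]),
            self._result("infogain", ["a|b", "c|d"]),
        ]
        assert (
            intersect_selections(results).key_pairs
            == intersect_selections(results[::-1]).key_pairs
        )

    def test_missing_method_is_error(self):
        with pytest.raises(ValidationError, match="boruta"):
            intersect_selections(
                [self._result(m, ["a|b"]) for m in ("auc", "infogain", "mrmr")]
            )
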