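"""Confusion-matrix rates, ROC/AUC sweeps, fold statistics and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from cystaug.evaluation import (
    ConfusionMatrix,
    ModelScoreTuple,
    UndefinedRateError,
    aggregate_folds,
    binary_tpr,
    confusion_matrix,
    macro_rates,
    micro_rates,
    rank_models,
    roc_auc,
    summarize_grid,
)


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.repeat(np.arange(4), 3)
        m = confusion_matrix(y, y, 4)
        assert np.array_equal(m.matrix, np.diag([3, 3, 3, 3]))
        assert m.trace == m.total == 12

    def test_hand_enumeration(self):
        m = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        assert np.array_equal(m.matrix, [[1, 1], [0, 1]])

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [], 2)
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)
        with pytest.raises(ValueError):
            confusion_matrix([0, 2], [0, 0], 2)


class TestRates:
    @pytest.mark.parametrize("pc, pi, expected", [(5, 0, 1.0), (3, 1, 0.75), (0, 7, 0.0)])
    def test_binary_tpr(self, pc, pi, expected):
        assert binary_tpr(pc, pi) == expected

    def test_binary_tpr_undefined(self):
        with pytest.raises(UndefinedRateError):
            binary_tpr(0, 0)

    def test_micro_rates_examples(self):
        assert micro_rates(ConfusionMatrix(np.eye(4, dtype=int))) == (1.0, 0.0)
        tpr, fpr = micro_rates(ConfusionMatrix([[3, 1], [2, 4]]))
        assert (tpr, fpr) == (0.7, 0.3)
        off = np.array([[0, 2], [3, 0]])
        assert micro_rates(ConfusionMatrix(off)) == (0.0, 1.0)

    def test_macro_diagonal(self):
        for conv in ("paper", "standard"):
            tpr, fpr, _, _ = macro_rates(ConfusionMatrix(np.diag([2, 3, 4, 5])), conv)
            assert tpr == 1.0 and fpr == 0.0

    def test_macro_uniform_matrix(self):
        tpr, _, tpr_n, _ = macro_rates(ConfusionMatrix(np.full((4, 4), 2)))
        assert tpr == 0.25
        assert np.allclose(tpr_n, 0.25)

    def test_macro_fpr_conventions_differ(self):
        m = ConfusionMatrix([[3, 1], [2, 4]])
        # class-1 false positives = 2; "paper" divides by G - column_1 = 10 - 5,
        # "standard" by G - row_1 = 10 - 4
        _, _, _, fpr_paper = macro_rates(m, "paper")
        _, _, _, fpr_std = macro_rates(m, "standard")
        assert fpr_paper[0] == pytest.approx(2 / 5)
        assert fpr_std[0] == pytest.approx(2 / 6)

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedRateError):
            macro_rates(ConfusionMatrix([[0, 0], [1, 1]]))
        with pytest.raises(UndefinedRateError):
            micro_rates(ConfusionMatrix(np.zeros((2, 2), dtype=int)))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 50), min_size=16, max_size=16).filter(lambda v: sum(v) > 0)
    )
    def test_micro_identity_and_accuracy(self, entries):
        """TPR_micro + FPR_micro == 1 and TPR_micro equals plain accuracy."""
        m = ConfusionMatrix(np.array(entries).reshape(4, 4))
        tpr, fpr = micro_rates(m)
        assert tpr + fpr == pytest.approx(1.0, abs=1e-12)
        # reconstruct label lists and compare against direct accuracy
        t, p = [], []
        for i in range(4):
            for j in range(4):
                t += [i] * m.matrix[i, j]
                p += [j] * m.matrix[i, j]
        assert tpr == pytest.approx(np.mean(np.array(t) == np.array(p)))


class TestRocAuc:
    def test_perfect_ordering(self):
        y = np.repeat(np.arange(4), 5)
        scores = np.full((20, 4), 0.1)
        scores[np.arange(20), y] = 0.7
        for avg in ("micro", "macro"):
            curve, auc = roc_auc(scores, y, avg)
            assert auc == 1.0
            assert curve.fpr[0] == 0.0 and curve.fpr[-1] == 1.0

    def test_label_independent_scores_give_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.integers(0, 4, n)
        s = rng.dirichlet(np.ones(4), n)
        for avg in ("micro", "macro"):
            _, auc = roc_auc(s, y, avg)
            assert abs(auc - 0.5) < 0.03

    def test_binary_auc_equals_pairwise_ordering_probability(self):
        """Exhaustive oracle: AUC = P(random positive scored above random
        negative), ties counting one half — checked on n <= 200 with ties."""
        rng = np.random.default_rng(1)
        for n in (10, 50, 200):
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s1 = np.round(rng.random(n), 1)  # coarse grid forces ties
            scores = np.stack([1 - s1, s1], axis=1)
            _, auc = roc_auc(scores, y, "macro")
            pos, neg = s1[y == 1], s1[y == 0]
            diff = pos[:, None] - neg[None, :]
            oracle = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_against_sklearn(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 4, 300)
        s = rng.dirichlet(np.ones(4), 300)
        onehot = np.eye(4)[y]
        _, micro = roc_auc(s, y, "micro")
        _, macro = roc_auc(s, y, "macro")
        assert micro == pytest.approx(roc_auc_score(onehot.ravel(), s.ravel()), abs=1e-10)
        assert macro == pytest.approx(
            roc_auc_score(y, s, multi_class="ovr", average="macro"), abs=1e-10
        )

    def test_degenerate_class_skipped_with_warning(self, caplog):
        y = np.array([0, 0, 1, 1])  # classes 2, 3 absent
        s = np.array([[0.7, 0.1, 0.1, 0.1]] * 2 + [[0.1, 0.7, 0.1, 0.1]] * 2)
        with caplog.at_level("WARNING", logger="cystaug.evaluation"):
            _, auc = roc_auc(s, y, "macro")
        assert auc == 1.0
        assert sum("skipped" in r.message for r in caplog.records) == 2


class TestFoldAggregation:
    def test_identical_folds(self):
        s = aggregate_folds([0.9] * 5, [0.9] * 5)
        assert s.mean_auc_micro == 0.9 and s.sigma_auc_micro == 0.0

    def test_two_folds_closed_form(self):
        s = aggregate_folds([0.8, 1.0], [0.8, 1.0])
        assert s.mean_auc_micro == pytest.approx(0.9)
        assert s.sigma_auc_micro == pytest.approx(0.1)  # population sd

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds([0.9], [0.9])


class TestRanking:
    def test_tie_broken_by_smaller_sigma(self):
        a = ModelScoreTuple(0.99, 0.99, 0.003, 0.003)
        b = ModelScoreTuple(0.99, 0.99, 0.001, 0.001)
        assert rank_models([a, b])[0] is b

    def test_higher_mean_first(self):
        a = ModelScoreTuple(0.97, 0.97, 0.001, 0.001)
        b = ModelScoreTuple(0.99, 0.99, 0.01, 0.01)
        assert rank_models([a, b])[0] is b

    def test_singleton_and_empty(self):
        t = ModelScoreTuple(0.9, 0.9, 0.0, 0.0)
        assert rank_models([t]) == [t]
        assert rank_models([]) == []

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        tuples = [
            ModelScoreTuple(*np.round(rng.random(2), 2), *np.round(rng.random(2), 3))
            for _ in range(20)
        ]
        ref = [t.astuple() for t in rank_models(tuples)]
        for _ in range(5):
            perm = [tuples[i] for i in rng.permutation(len(tuples))]
            assert [t.astuple() for t in rank_models(perm)] == ref


class TestGridSummary:
    def test_single_tuple(self):
        t = ModelScoreTuple(0.9, 0.9, 0.01, 0.01)
        s = summarize_grid([t])
        assert s["mean_auc_micro_mean"] == s["mean_auc_micro_median"] == 0.9
        assert s["mean_auc_micro_std"] == 0.0

    def test_median_of_three(self):
        ts = [ModelScoreTuple(v, v, 0.0, 0.0) for v in (0.9, 0.95, 1.0)]
        assert summarize_grid(ts)["mean_auc_micro_median"] == 0.95

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(4)
        vals = rng.random(10)
        sigs = rng.random(10) / 10
        ts = [ModelScoreTuple(v, v, s, s) for v, s in zip(vals, sigs)]
        out = summarize_grid(ts)
        assert out["mean_auc_micro_mean"] == pytest.approx(vals.mean())
        assert out["sigma_auc_micro_std"] == pytest.approx(sigs.std())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_grid([])
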