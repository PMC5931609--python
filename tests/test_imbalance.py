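"""Resampling and imbalance-aware metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csom import (
    NON_CONCLUSIVE,
    Prediction,
    balanced_target_counts,
    compute_metrics,
    random_undersample,
    smote,
    tally,
)
from csom.imbalance import AllNonConclusiveError, ConfusionResult, ResamplingError

from conftest import make_dataset


def pred(decision, probs=None):
    if probs is None:
        probs = [1.0, 0.0]
    return Prediction(probabilities=np.asarray(probs, dtype=float), decision=decision)


class TestSmote:
    def test_synthetic_point_is_convex_combination(self):
        data = make_dataset(
            [[0.0, 0.0], [1.0, 1.0], [5.0, 5.0], [6.0, 6.0], [7.0, 7.0]],
            ["min", "min", "maj", "maj", "maj"],
        )
        out = smote(data, {"min": 3, "maj": 3}, k=1, seed=0)
        new = out.X[5]
        assert new[0] == pytest.approx(new[1])
        assert 0.0 <= new[0] <= 1.0

    def test_coincident_points_reproduce_themselves(self):
        data = make_dataset([[2.0, 3.0], [2.0, 3.0], [9.0, 9.0]], ["m", "m", "M"])
        out = smote(data, {"m": 5}, k=1, seed=1)
        assert np.allclose(out.X[3:], [2.0, 3.0])

    def test_matching_targets_is_identity(self):
        data = make_dataset([[0.0], [1.0], [2.0]], ["a", "a", "b"])
        out = smote(data, {"a": 2, "b": 1}, seed=0)
        assert np.array_equal(out.X, data.X)
        assert out.labels == data.labels

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_counts_purity_and_bounding_box(self, seed):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(5, 1, (40, 3))])
        data = make_dataset(X, ["min"] * 8 + ["maj"] * 40)
        out = smote(data, balanced_target_counts(data), seed=seed)
        counts = out.class_counts()
        assert counts == {"min": 40, "maj": 40}
        # originals preserved verbatim, synthetic rows carry only the minority label
        assert np.array_equal(out.X[:48], X)
        assert all(ls == frozenset(["min"]) for ls in out.labels[48:])
        lo, hi = X[:8].min(axis=0), X[:8].max(axis=0)
        assert np.all(out.X[48:] >= lo - 1e-12) and np.all(out.X[48:] <= hi + 1e-12)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(0)
        data = make_dataset(rng.normal(size=(20, 2)), ["a"] * 5 + ["b"] * 15)
        a = smote(data, {"a": 15}, seed=3)
        b = smote(data, {"a": 15}, seed=3)
        assert np.array_equal(a.X, b.X)

    def test_singleton_class_with_deficit_rejected_by_name(self):
        data = make_dataset([[0.0], [1.0], [2.0]], ["solo", "big", "big"])
        with pytest.raises(ResamplingError, match="solo"):
            smote(data, {"solo": 4}, seed=0)

    def test_shrinking_target_rejected(self):
        data = make_dataset([[0.0], [1.0], [2.0]], ["a", "a", "a"])
        with pytest.raises(ResamplingError):
            smote(data, {"a": 2}, seed=0)


class TestRandomUndersample:
    def test_exact_counts_all_originals(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(110, 2))
        data = make_dataset(X, ["maj"] * 100 + ["min"] * 10)
        out = random_undersample(data, {"maj": 10}, seed=0)
        assert out.class_counts() == {"maj": 10, "min": 10}
        rows = {tuple(r) for r in X}
        assert all(tuple(r) in rows for r in out.X)

    def test_deterministic_per_seed(self):
        data = make_dataset(np.arange(40).reshape(20, 2), ["a"] * 20)
        a = random_undersample(data, {"a": 7}, seed=5)
        b = random_undersample(data, {"a": 7}, seed=5)
        assert np.array_equal(a.X, b.X)

    def test_target_equal_to_current_is_identity(self):
        data = make_dataset([[1.0], [2.0]], ["a", "a"])
        out = random_undersample(data, {"a": 2}, seed=0)
        assert np.array_equal(out.X, data.X)

    def test_excess_target_rejected(self):
        data = make_dataset([[1.0]], ["a"])
        with pytest.raises(ResamplingError):
            random_undersample(data, {"a": 2}, seed=0)


class TestTally:
    names = ["a", "b"]

    def test_all_correct_gives_diagonal(self):
        preds = [pred("a"), pred("a"), pred("b")]
        c = tally(["a", "a", "b"], preds, self.names)
        assert np.array_equal(c.matrix, [[2, 0], [0, 1]])
        assert c.n_nonconclusive == 0

    def test_all_nonconclusive_gives_zero_matrix(self):
        preds = [pred(NON_CONCLUSIVE)] * 4
        c = tally(["a", "b", "a", "b"], preds, self.names)
        assert c.matrix.sum() == 0 and c.n_nonconclusive == 4

    def test_mixed_conserves_counts(self):
        preds = [pred("a")] * 4 + [pred("b")] * 3 + [pred(NON_CONCLUSIVE)] * 3
        c = tally(["a"] * 10, preds, self.names)
        assert c.matrix.sum() == 7
        assert c.matrix.sum() + c.n_nonconclusive == c.n_total == 10

    def test_multilabel_truth_credits_any_hit(self):
        c = tally([frozenset(["a", "b"])], [pred("b")], self.names)
        assert c.matrix[1, 1] == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            tally(["zz"], [pred("a")], self.names)


def confusion(matrix, n_out=0, names=None):
    m = np.asarray(matrix, dtype=int)
    if names is None:
        names = [f"c{i}" for i in range(m.shape[0])]
    return ConfusionResult(
        matrix=m, n_nonconclusive=n_out, n_total=int(m.sum()) + n_out,
        class_names=names,
    )


class TestComputeMetrics:
    def test_two_class_closed_form(self):
        rep = compute_metrics(confusion([[50, 0], [25, 25]]))
        assert rep.mean_recall == pytest.approx(0.75)
        assert rep.gmean_recall == pytest.approx(np.sqrt(0.5))
        assert rep.accuracy == pytest.approx(0.75)

    def test_perfect_diagonal_scores_one(self):
        rep = compute_metrics(confusion([[10, 0], [0, 3]]))
        assert rep.accuracy == rep.mean_recall == rep.gmean_recall == rep.f_measure == 1.0

    def test_uniform_confusion_closed_form(self):
        rep = compute_metrics(confusion([[1, 1], [1, 1]]))
        assert rep.f_measure == pytest.approx(0.5)
        assert rep.mean_recall == pytest.approx(0.5)

    def test_pct_out_accounting(self):
        rep = compute_metrics(confusion([[7, 0], [0, 0]], n_out=3))
        assert rep.pct_out == pytest.approx(30.0)

    def test_all_nonconclusive_raises_distinct_error(self):
        with pytest.raises(AllNonConclusiveError):
            compute_metrics(confusion([[0, 0], [0, 0]], n_out=5))

    def test_mean_recall_invariant_to_class_duplication_accuracy_not(self):
        """Duplicating every member of one class leaves per-class recalls
        (hence mean recall) unchanged while accuracy shifts — the reason
        recall-based means suit imbalanced data."""
        base = confusion([[40, 10], [5, 15]])
        doubled = confusion([[80, 20], [5, 15]])
        a, b = compute_metrics(base), compute_metrics(doubled)
        assert a.mean_recall == pytest.approx(b.mean_recall)
        assert a.accuracy != pytest.approx(b.accuracy)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_gmean_never_exceeds_mean_recall(self, cells):
        m = np.array(cells).reshape(2, 2)
        if m.sum() == 0:
            return
        rep = compute_metrics(confusion(m.tolist()))
        assert rep.gmean_recall <= rep.mean_recall + 1e-12
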