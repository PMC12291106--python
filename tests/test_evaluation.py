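"""Cross-validation designs, selection, importances and classification metrics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rulefinder.evaluation import (
    ForwardSelector,
    ModelSpec,
    classification_report,
    feature_importance,
    forward_select,
    kfold_cv,
    loo_eval,
    lpo_balanced_splits,
    rfecv_select,
    top_feature_frequency,
)

FAST = ModelSpec(n_estimators=25)


def _balanced(n, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    return rng, y


class TestKFold:
    def test_perfectly_separating_feature_scores_one(self):
        _, y = _balanced(20)
        report = kfold_cv(y.reshape(-1, 1).astype(float), y, FAST, seed=0)
        assert report.accuracy_mean == 1.0

    def test_same_seed_reproduces_per_split_accuracies(self):
        rng, y = _balanced(20, 1)
        X = rng.normal(size=(20, 3))
        a = kfold_cv(X, y, FAST, seed=7)
        b = kfold_cv(X, y, FAST, seed=7)
        assert a.per_split == b.per_split

    def test_noise_feature_null_accuracy(self):
        """Pure-noise features on balanced labels: mean accuracy near 1/2."""
        _, y = _balanced(36)
        accs = []
        for seed in range(20):
            X = np.random.default_rng(seed + 100).normal(size=(36, 1))
            accs.append(kfold_cv(X, y, FAST, seed=seed).accuracy_mean)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError):
            kfold_cv(np.zeros((10, 1)), np.zeros(10, dtype=int), FAST, seed=0)


class TestLoo:
    def test_split_count_per_seed(self):
        rng, y = _balanced(36, 2)
        X = rng.normal(size=(36, 2))
        report = loo_eval(X, y, FAST, seeds=[0])
        assert len(report.per_split) == 36

    def test_nine_seeds_are_reported(self):
        _, y = _balanced(12)
        report = loo_eval(y.reshape(-1, 1).astype(float), y, FAST, seeds=range(9))
        assert len(report.seeds) == 9
        assert len(report.per_split) == 9 * 12

    def test_perfect_feature_has_zero_seed_spread(self):
        _, y = _balanced(12)
        report = loo_eval(y.reshape(-1, 1).astype(float), y, FAST, seeds=range(3))
        assert report.accuracy_mean == 1.0
        assert report.accuracy_sd == 0.0


class TestLpoBalancedSplits:
    def test_pool_size_and_distinctness(self):
        """9 high + 9 low: 50 distinct splits from the C(9,2)^2 = 1296 pool."""
        y = np.array([1] * 9 + [0] * 9)
        splits = lpo_balanced_splits(y, p=4, n_splits=50, seed=0)
        assert len(splits) == 50
        highs = set(range(9))
        pool = {
            tuple(sorted(h + l))
            for h in itertools.combinations(range(9), 2)
            for l in itertools.combinations(range(9, 18), 2)
        }
        assert len(pool) == math.comb(9, 2) ** 2 == 1296
        seen = set()
        for train, test in splits:
            key = tuple(test.tolist())
            assert key in pool
            assert key not in seen
            seen.add(key)
            assert len(set(test) & highs) == 2
            # exact partition
            assert sorted(np.concatenate([train, test]).tolist()) == list(range(18))

    def test_unbalanced_classes_raise(self):
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError):
            lpo_balanced_splits(y, p=4, n_splits=5, seed=0)

    def test_too_many_splits_names_maximum(self):
        y = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError, match="1"):
            lpo_balanced_splits(y, p=4, n_splits=2, seed=0)

    def test_same_seed_same_splits(self):
        y = np.array([1] * 9 + [0] * 9)
        a = lpo_balanced_splits(y, seed=5)
        b = lpo_balanced_splits(y, seed=5)
        assert all((ta == tb).all() for (_, ta), (_, tb) in zip(a, b))


class TestForwardSelect:
    def test_label_copy_selected_first(self):
        rng, y = _balanced(16, 3)
        X = pd.DataFrame({"copy": y.astype(float), "noise": rng.normal(size=16)})
        selected = forward_select(X, y, FAST, seed=0)
        assert selected[0] == "copy"

    def test_constant_candidates_do_not_crash(self):
        _, y = _balanced(10)
        X = pd.DataFrame({"c1": np.ones(10), "c2": np.ones(10)})
        selected = forward_select(X, y, FAST, seed=0)
        assert len(selected) <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_accuracy_trace_is_non_decreasing(self, seed):
        rng, y = _balanced(16, seed)
        X = pd.DataFrame(rng.normal(size=(16, 4)), columns=list("abcd"))
        X["signal"] = y + rng.normal(scale=0.3, size=16)
        _, trace = forward_select(X, y, FAST, seed=0, return_trace=True)
        assert all(b >= a for a, b in zip(trace, trace[1:]))

    def test_selector_estimator_masks_columns(self):
        rng, y = _balanced(16, 9)
        X = pd.DataFrame({"copy": y.astype(float), "noise": rng.normal(size=16)})
        sel = ForwardSelector(FAST, max_features=1, seed=0).fit(X, y)
        assert sel.selected_ == ["copy"]
        assert sel.transform(X).shape[1] == 1


class TestTopFeatureFrequency:
    def test_always_first_counts_every_split(self):
        sels = [["a", "b", "c", "d"]] * 50
        assert top_feature_frequency(sels)["a"] == 50

    def test_rank_four_never_counts(self):
        sels = [["a", "b", "c", "d"]] * 50
        assert top_feature_frequency(sels, top_k=3).get("d", 0) == 0

    def test_total_bounded_by_splits_times_k(self):
        rng = np.random.default_rng(0)
        sels = [list(rng.permutation(list("abcdef")))[: rng.integers(1, 6)] for _ in range(50)]
        counts = top_feature_frequency(sels, top_k=3)
        assert sum(counts.values()) <= 150


class TestRfecv:
    def test_label_copy_retained_across_seeds(self):
        """Signal among noise: the separating feature survives elimination."""
        _, y = _balanced(24)
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed + 500)
            X = pd.DataFrame(rng.normal(size=(24, 3)), columns=["n1", "n2", "n3"])
            X.insert(0, "copy", y.astype(float))
            if "copy" in rfecv_select(X, y, FAST, seed=seed):
                kept += 1
        assert kept >= 18

    def test_same_seed_same_subset(self):
        rng, y = _balanced(20, 4)
        X = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        assert rfecv_select(X, y, FAST, seed=3) == rfecv_select(X, y, FAST, seed=3)


class TestFeatureImportance:
    def test_separating_feature_dominates(self):
        rng, y = _balanced(20, 5)
        X = pd.DataFrame({"sig": y.astype(float), "n1": rng.normal(size=20), "n2": rng.normal(size=20)})
        rep = feature_importance(FAST, X, y, seed=0, backend="permutation")
        assert max(rep.values, key=lambda k: abs(rep.values[k])) == "sig"
        assert rep.backend == "permutation"

    def test_zero_variance_feature_scores_zero(self):
        _, y = _balanced(20)
        X = pd.DataFrame({"sig": y.astype(float), "const": np.ones(20)})
        rep = feature_importance(FAST, X, y, seed=0, backend="permutation")
        assert rep.values["const"] == 0.0

    def test_duplicated_feature_shares_attribution(self):
        rng, y = _balanced(20, 6)
        noise = rng.normal(size=20)
        single = feature_importance(
            ModelSpec(n_estimators=50), pd.DataFrame({"f": y.astype(float), "noise": noise}), y, seed=0, backend="permutation"
        )
        dup = feature_importance(
            ModelSpec(n_estimators=50),
            pd.DataFrame({"f": y.astype(float), "f2": y.astype(float), "noise": noise}),
            y,
            seed=0,
            backend="permutation",
        )
        # each copy carries less than the lone feature; jointly they retain
        # a substantial share of its attribution
        assert dup.values["f"] <= single.values["f"]
        assert dup.values["f2"] <= single.values["f"]
        assert dup.values["f"] + dup.values["f2"] >= 0.5 * single.values["f"]


class TestClassificationReport:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0])
        rep = classification_report(y, y, y.astype(float))
        assert all(rep[k] == 1.0 for k in ("accuracy", "recall", "precision", "f1", "roc_auc"))

    def test_all_negative_predictions_on_balanced_truth(self):
        y = np.array([0, 1] * 5)
        rep = classification_report(y, np.zeros(10, dtype=int))
        assert rep["recall"] == 0.0
        assert rep["accuracy"] == 0.5

    def test_matches_confusion_table_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=40)
        pred = rng.integers(0, 2, size=40)
        tp = int(((y == 1) & (pred == 1)).sum())
        fp = int(((y == 0) & (pred == 1)).sum())
        fn = int(((y == 1) & (pred == 0)).sum())
        tn = int(((y == 0) & (pred == 0)).sum())
        rep = classification_report(y, pred)
        assert rep["accuracy"] == pytest.approx((tp + tn) / 40)
        assert rep["recall"] == pytest.approx(tp / (tp + fn))
        assert rep["precision"] == pytest.approx(tp / (tp + fp))
        prec, rec = rep["precision"], rep["recall"]
        assert rep["f1"] == pytest.approx(2 * prec * rec / (prec + rec))

    def test_single_class_truth_has_no_auc(self):
        rep = classification_report([1, 1, 1], [1, 0, 1], [0.9, 0.1, 0.8])
        assert rep["roc_auc"] is None
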