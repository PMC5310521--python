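"""Cross-validation protocol: stratification, descriptor selection, learners, scoring."""

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score

import vehitox as vt
from vehitox.labelling import DatasetCounts, ModellingDataset
from vehitox.modelling import (
    ModelConfig,
    StratificationError,
    UndefinedMetric,
    descriptor_importance,
    pls_component_cap,
)


def make_dataset(X, y, names=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    return ModellingDataset(
        vehicle_a="saline",
        vehicle_b="CMC",
        strategy=None,
        threshold_pct=None,
        compound_ids=[f"c{i}" for i in range(len(y))],
        labels=y,
        features=X,
        feature_names=names or [f"f{j}" for j in range(X.shape[1])],
        counts=DatasetCounts(int((y == 0).sum()), int((y == 1).sum()), 0, 0, 0),
    )


def separable_dataset(n=100, n_noise=20, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.repeat([0, 1], n // 2))
    X = np.column_stack([y, rng.random((n, n_noise))])
    return make_dataset(X, y)


def null_dataset(n=60, n_features=50, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.permutation(np.repeat([0, 1], n // 2))
    return make_dataset(rng.integers(0, 2, size=(n, n_features)), y)


class TestStratifiedFolds:
    def test_exact_divisibility(self, rng):
        labels = np.repeat([0, 1], [60, 40])
        folds = vt.stratified_folds(labels, 10, rng)
        for fold in folds:
            assert len(fold) == 10
            assert (labels[fold] == 0).sum() == 6
            assert (labels[fold] == 1).sum() == 4

    def test_123_compounds_69_54(self, rng):
        labels = np.repeat([0, 1], [69, 54])
        folds = vt.stratified_folds(labels, 10, rng)
        assert sorted(np.concatenate(folds)) == list(range(123))
        for fold in folds:
            assert len(fold) in (12, 13)
            assert abs((labels[fold] == 0).sum() - 6.9) <= 1
            assert abs((labels[fold] == 1).sum() - 5.4) <= 1

    def test_same_seed_same_folds(self):
        labels = np.repeat([0, 1], [31, 30])
        f1 = vt.stratified_folds(labels, 10, np.random.default_rng(5))
        f2 = vt.stratified_folds(labels, 10, np.random.default_rng(5))
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_class_smaller_than_k_is_an_error(self, rng):
        with pytest.raises(StratificationError):
            vt.stratified_folds(np.repeat([0, 1], [50, 5]), 10, rng)


class TestSelectDescriptors:
    def test_label_copy_ranks_first(self, rng):
        y = rng.integers(0, 2, 40)
        X = np.column_stack([rng.random((40, 3)), y])
        assert vt.select_descriptors(X, y, 1)[0] == 3

    def test_constant_descriptor_never_selected(self, rng):
        y = rng.integers(0, 2, 40)
        X = np.column_stack([np.full(40, 7.0), y.astype(float)])
        with pytest.warns(UserWarning):
            selected = vt.select_descriptors(X, y, 2)
        assert list(selected) == [1]

    def test_planted_correlation_ordering(self):
        # descriptors built as label + increasing noise: known |r| ordering
        rng = np.random.default_rng(3)
        y = rng.permutation(np.repeat([0, 1], 100)).astype(float)
        X = np.column_stack(
            [y + rng.normal(0, s, 200) for s in (2.0, 0.1, 0.7)]
        )
        oracle = np.argsort([-abs(np.corrcoef(X[:, j], y)[0, 1]) for j in range(3)])
        assert list(vt.select_descriptors(X, y, 2)) == list(oracle[:2])


class TestDescriptorBudget:
    @pytest.mark.parametrize("method, n_train, expected", [("dt", 110, 11), ("rf", 83, 8)])
    def test_one_tenth_of_training_set(self, method, n_train, expected):
        assert vt.descriptor_budget(method, n_train) == expected

    def test_pls_grid_and_component_cap(self):
        assert vt.descriptor_budget("pls", 110) == (5, 10, 20, 50)
        assert pls_component_cap(123) == 12


class TestBalancedAccuracy:
    def test_confusion_matrix_example(self):
        # TP=3, FN=1, TN=2, FP=2 -> (0.75 + 0.5) / 2
        y_true = [1, 1, 1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0, 1, 1]
        assert vt.balanced_accuracy(y_true, y_pred) == pytest.approx(0.625)
        assert vt.balanced_accuracy(y_true, y_pred) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )

    def test_degenerate_predictions_score_half(self):
        assert vt.balanced_accuracy([0, 0, 1, 1], [1, 1, 1, 1]) == pytest.approx(0.5)

    def test_invariant_to_class_relabelling(self, rng):
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        if len(set(y_true)) == 2:
            assert vt.balanced_accuracy(y_true, y_pred) == pytest.approx(
                vt.balanced_accuracy(1 - y_true, 1 - y_pred)
            )

    def test_missing_class_is_undefined(self):
        with pytest.raises(UndefinedMetric):
            vt.balanced_accuracy([1, 1, 1], [1, 0, 1])


class TestCrossValidate:
    @pytest.mark.parametrize("method", ["dt", "rf", "pls"])
    def test_separable_data_scores_one(self, method):
        config = ModelConfig(method=method, seed=1, rf_n_trees=25)
        run = vt.cross_validate(separable_dataset(), config)
        assert run.balanced_accuracy == pytest.approx(1.0)

    def test_each_compound_predicted_exactly_once(self):
        run = vt.cross_validate(separable_dataset(), ModelConfig("dt", seed=2))
        assert (run.oof_predictions >= 0).all()
        assert set(run.fold_assignment) == set(range(10))
        assert np.bincount(run.fold_assignment).sum() == 100

    def test_same_seed_identical_run(self):
        dataset = null_dataset(seed=4)
        r1 = vt.cross_validate(dataset, ModelConfig("dt", seed=9))
        r2 = vt.cross_validate(dataset, ModelConfig("dt", seed=9))
        assert r1.balanced_accuracy == r2.balanced_accuracy
        assert np.array_equal(r1.oof_predictions, r2.oof_predictions)

    def test_null_data_scores_near_half_on_average(self):
        accs = [
            vt.cross_validate(null_dataset(seed=s), ModelConfig("dt", seed=s)).balanced_accuracy
            for s in range(30)
        ]
        assert abs(float(np.mean(accs)) - 0.5) < 0.05

    def test_pls_reports_grid_choice(self):
        run = vt.cross_validate(separable_dataset(n_noise=60), ModelConfig("pls", seed=3))
        assert run.pls_n_descriptors in (5, 10, 20, 50)
        assert set(run.pls_grid_accuracies) == {5, 10, 20, 50}


class TestRfDistribution:
    def test_count_and_determinism(self):
        dataset = separable_dataset(n=60, seed=6)
        config = ModelConfig("rf", seed=4, rf_n_seeds=5, rf_n_trees=25)
        d1 = vt.rf_distribution(dataset, config)
        d2 = vt.rf_distribution(dataset, config)
        assert len(d1) == 5
        assert np.array_equal(d1, d2)
        assert d1 == pytest.approx(np.ones(5))  # separable -> every seed perfect


class TestDescriptorImportance:
    def test_planted_descriptor_ranks_first_in_both_directions(self):
        rng = np.random.default_rng(8)
        y = rng.permutation(np.repeat([0, 1], 50))
        X = np.column_stack([y.astype(float), rng.random((100, 30))])
        dataset = make_dataset(X, y)
        table = descriptor_importance(dataset, n_models=10, config=ModelConfig("rf", seed=2, rf_n_trees=25))
        assert table.loc["f0", "rank_class_a"] == 1
        assert table.loc["f0", "rank_class_b"] == 1
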