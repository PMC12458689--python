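"""Metrics, CV hygiene, undersampling, baselines, and model persistence."""
import numpy as np
import pytest

from sigsel import tpe
from sigsel.datasets import LabeledDataset, Task
from sigsel.errors import CompatibilityError, UndefinedError, UsageError
from sigsel.featurization import FeatureMatrix, RepresentationKind, select_features
from sigsel.modeling import (
    Algorithm,
    ModelConfig,
    classical_cv,
    classification_metrics,
    freeze_hyperparameters,
    nested_cv,
    regression_metrics,
    run_baselines,
    undersample_indices,
)

from conftest import make_classification_features
from oracle_helpers import brute_confusion_metrics, confusion_to_labels

TINY_TREE_SPACE = {"n_estimators": tpe.Int(20, 60), "max_depth": tpe.Int(3, 10)}


class TestClassificationMetrics:
    def test_perfect(self):
        y = np.array([0, 1, 0, 1, 1])
        score = y.astype(float)
        m = classification_metrics(y, y, score)
        assert m["F1"] == m["PRECISION"] == m["RECALL"] == m["MCC"] == 1.0
        assert m["ROC_AUC"] == 1.0

    def test_mcc_formula_example(self):
        # confusion table TP=84, FN=6, FP=3, TN=7 evaluated by the raw formula
        cm = [[7, 3], [6, 84]]  # rows: truth (neg, pos)
        y_true, y_pred, score = confusion_to_labels(cm)
        m = classification_metrics(y_true, y_pred, score[:, 1])
        expected = (84 * 7 - 3 * 6) / np.sqrt((84 + 3) * (84 + 6) * (7 + 3) * (7 + 6))
        assert m["MCC"] == pytest.approx(expected, abs=1e-12)

    def test_single_class_prediction_mcc_zero(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.zeros(4, dtype=int)
        m = classification_metrics(y_true, y_pred, np.full(4, 0.5))
        assert m["MCC"] == 0.0

    def test_missing_score(self):
        with pytest.raises(UsageError):
            classification_metrics([0, 1], [0, 1], None)

    def test_three_class_oracle_random_tables(self):
        """Weighted F1/precision/recall and multiclass MCC agree exactly with
        brute-force formula evaluation on random 3-class confusion tables
        (the exhaustive sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(0)
        for _ in range(150):
            cm = rng.integers(0, 11, size=(3, 3))
            while (cm.sum(axis=1) == 0).any():
                cm = rng.integers(0, 11, size=(3, 3))
            y_true, y_pred, score = confusion_to_labels(cm.tolist())
            ours = classification_metrics(y_true, y_pred, score)
            expected = brute_confusion_metrics(cm.tolist())
            for key, val in expected.items():
                assert ours[key] == pytest.approx(val, abs=1e-12), (key, cm)

    def test_multiclass_auc_matches_sklearn_on_probabilities(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 60)
        proba = rng.dirichlet(np.ones(3), size=60)
        ours = classification_metrics(y, proba.argmax(1), proba)["ROC_AUC"]
        ref = roc_auc_score(y, proba, multi_class="ovr", average="weighted")
        assert ours == pytest.approx(ref, abs=1e-12)


class TestRegressionMetrics:
    def test_perfect_and_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        assert regression_metrics(y, y) == {"RMSE": 0.0, "R2": 1.0}
        m = regression_metrics(y, np.full(3, y.mean()))
        assert m["R2"] == pytest.approx(0.0)

    def test_hand_example(self):
        m = regression_metrics([5, 6, 7], [5, 7, 6])
        assert m["RMSE"] == pytest.approx(np.sqrt(2 / 3))

    def test_zero_variance(self):
        with pytest.raises(UndefinedError):
            regression_metrics([2.0, 2.0], [1.0, 3.0])


class TestUndersampling:
    def test_balances_to_minority(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 90 + [1] * 25 + [2] * 10)
        idx = undersample_indices(y, rng)
        _, counts = np.unique(y[idx], return_counts=True)
        assert (counts == 10).all()
        assert len(set(idx)) == len(idx)


class TestNestedCV:
    def test_hygiene_and_performance(self, imbalanced_binary):
        ds, fm = imbalanced_binary
        cfg = ModelConfig(Algorithm.EXTRA_TREES, ds.task, search_space=TINY_TREE_SPACE, seed=0)
        cv = nested_cv(ds, fm, cfg, n_trials=5)
        # leakage: outer folds partition the data with no overlap
        n = len(ds)
        y = ds.y
        for tr, te in cv.diagnostics["outer_folds"]:
            assert not set(tr) & set(te)
            assert len(tr) + len(te) == n
            # stratification within +-1 sample per class
            for cls in np.unique(y):
                expected = np.sum(y[te] == cls) * 5
                assert abs(np.sum(y == cls) - expected) <= 5
        # undersampled training portions are exactly balanced
        for counts in cv.diagnostics["fit_class_counts"]:
            assert len(set(counts.values())) == 1
        # selection statistics recomputable from training rows alone
        for (tr, _), retained in zip(
            cv.diagnostics["outer_folds"], cv.diagnostics["retained_outer"]
        ):
            expected, _ = select_features(fm.rows(tr))
            assert list(expected) == retained
        # separable Gaussian clusters: near-perfect ranking
        assert cv.mean["ROC_AUC"] >= 0.95
        assert len(cv.per_fold) == 5

    def test_scaler_fitted_on_training_rows_only(self, separable_binary):
        ds, fm = separable_binary
        cfg = ModelConfig(
            Algorithm.SVM, ds.task, search_space={"C": tpe.Float(0.1, 10, log=True)}, seed=1
        )
        cv = nested_cv(ds, fm, cfg, n_trials=3)
        for (tr, _), retained, mean in zip(
            cv.diagnostics["outer_folds"],
            cv.diagnostics["retained_outer"],
            cv.diagnostics["scaler_mean"],
        ):
            expected = fm.values[np.ix_(tr, retained)].mean(axis=0)
            assert np.allclose(expected, mean)

    def test_single_class_rejected(self):
        ds = LabeledDataset(1, [f"C{'C'*i}" for i in range(20)], np.zeros(20, int), Task.BINARY_ACTIVITY)
        fm = FeatureMatrix(np.random.default_rng(0).normal(size=(20, 3)), ["a", "b", "c"],
                           RepresentationKind.DESC_COMPACT_2D)
        with pytest.raises(UsageError):
            nested_cv(ds, fm, ModelConfig(Algorithm.EXTRA_TREES, ds.task, TINY_TREE_SPACE))

    def test_row_mismatch_rejected(self, separable_binary):
        ds, fm = separable_binary
        with pytest.raises(UsageError):
            nested_cv(ds, fm.rows(range(10)), ModelConfig(Algorithm.EXTRA_TREES, ds.task, TINY_TREE_SPACE))


class TestClassicalCV:
    def test_reproducible_and_fixed(self, imbalanced_binary):
        ds, fm = imbalanced_binary
        cfg = ModelConfig(
            Algorithm.EXTRA_TREES, ds.task, search_space=TINY_TREE_SPACE,
            fixed_params={"n_estimators": 40, "max_depth": 6}, seed=4,
        )
        a = classical_cv(ds, fm, cfg)
        b = classical_cv(ds, fm, cfg)
        assert a.per_fold == b.per_fold
        assert a.diagnostics["tuned_params"] == {}  # nothing left to tune

    def test_requires_fixed_params(self, imbalanced_binary):
        ds, fm = imbalanced_binary
        cfg = ModelConfig(Algorithm.EXTRA_TREES, ds.task, search_space=TINY_TREE_SPACE)
        with pytest.raises(UsageError):
            classical_cv(ds, fm, cfg)

    def test_leaked_label_gives_perfect_mcc(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 150)
        X = np.column_stack([y.astype(float), rng.normal(size=(150, 3))])
        ds = LabeledDataset(1, [f"C{'C'*i}" for i in range(150)], y, Task.BINARY_ACTIVITY)
        fm = FeatureMatrix(X, ["leak", "a", "b", "c"], RepresentationKind.DESC_COMPACT_2D)
        cfg = ModelConfig(
            Algorithm.EXTRA_TREES, ds.task, search_space=TINY_TREE_SPACE,
            fixed_params={"n_estimators": 30}, seed=0,
        )
        cv = classical_cv(ds, fm, cfg, select=False)
        assert cv.mean["MCC"] == 1.0

    def test_narrowed_tuning_runs(self, imbalanced_binary):
        ds, fm = imbalanced_binary
        cfg = ModelConfig(
            Algorithm.EXTRA_TREES, ds.task, search_space=TINY_TREE_SPACE,
            fixed_params={"max_depth": 6}, seed=4,
        )
        cv = classical_cv(ds, fm, cfg, n_trials=4)
        assert "n_estimators" in cv.diagnostics["tuned_params"]
        assert "n_estimators" in cv.diagnostics["narrowed_space"]


class TestFreeze:
    def test_categorical_majority_and_numeric_median(self):
        space = {
            "criterion": tpe.Categorical(["gini", "entropy"]),
            "n_estimators": tpe.Int(100, 1000),
            "max_depth": tpe.Int(3, 30),
        }
        folds = [
            {"criterion": "gini", "n_estimators": 400, "max_depth": 5},
            {"criterion": "gini", "n_estimators": 420, "max_depth": 22},
            {"criterion": "gini", "n_estimators": 380, "max_depth": 9},
            {"criterion": "entropy", "n_estimators": 410, "max_depth": 28},
            {"criterion": "entropy", "n_estimators": 390, "max_depth": 3},
        ]
        fixed, narrowed = freeze_hyperparameters(folds, space)
        assert fixed["criterion"] == "gini"  # modal in 3/5 folds
        assert fixed["n_estimators"] == 400  # all within +-25% of the median
        assert "max_depth" in narrowed  # inconsistent -> narrowed range
        assert (narrowed["max_depth"].low, narrowed["max_depth"].high) == (3, 28)


class TestBaselines:
    def test_battery_and_dummies(self, imbalanced_binary):
        ds, fm = imbalanced_binary
        fm = FeatureMatrix(fm.values, ["MolLogP"] + fm.names[1:], fm.kind)
        results = run_baselines(ds, fm, seed=0)
        assert {"logistic_regression", "1nn", "decision_tree", "logreg_slogp",
                "majority_dummy", "uniform_dummy"} <= set(results)
        # majority dummy never recalls the minority class: weighted recall
        # equals the majority prevalence and MCC is 0
        assert results["majority_dummy"].mean["MCC"] == 0.0

    def test_uniform_dummy_auc_near_half(self):
        ds, fm = make_classification_features(n=4000, n_classes=2, seed=11, dataset_id=1)
        results = run_baselines(ds, fm, seed=0)
        assert 0.45 <= results["uniform_dummy"].mean["ROC_AUC"] <= 0.55

    def test_median_dummy(self):
        rng = np.random.default_rng(0)
        y = rng.normal(6, 1, 120)
        ds = LabeledDataset(1, [f"C{'C'*i}" for i in range(120)], y, Task.REGRESSION)
        fm = FeatureMatrix(rng.normal(size=(120, 4)), list("abcd"), RepresentationKind.DESC_COMPACT_2D)
        results = run_baselines(ds, fm, seed=0)
        assert set(results) == {"median_dummy"}
        assert results["median_dummy"].mean["R2"] <= 0.05
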