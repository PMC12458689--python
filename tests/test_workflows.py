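"""Workflow routing, oracle consistency, and external reporting."""
import itertools

import numpy as np
import pytest

from sigsel.errors import UsageError
from sigsel.labeling import MulticlassLabel, SelectivityClass, selectivity_class
from sigsel.workflows import (
    combine_two_step,
    external_report,
    predict_one_step_multiclass,
    predict_two_step_classification,
    predict_two_step_regression,
)

from oracle_helpers import brute_selectivity


class _OracleModel:
    """Duck-typed stand-in for a FittedModel: predicts from a lookup table."""

    def __init__(self, mapping, task=None):
        self.mapping = mapping
        self.task = task

    def predict_smiles(self, smiles_list):
        return np.array([self.mapping[s] for s in smiles_list])


class TestTwoStepClassification:
    def test_routing_totality(self):
        """Exactly one class for every activity x selectivity outcome."""
        for a1, a2 in itertools.product([0, 1], repeat=2):
            if a1 and a2:
                for s1, s2 in itertools.product([0, 1], repeat=2):
                    cls, flag = combine_two_step(a1, a2, s1, s2)
                    assert isinstance(cls, SelectivityClass)
                    assert cls != SelectivityClass.UNDEFINED
                    assert flag == (s1 == s2 == 1)
            else:
                cls, flag = combine_two_step(a1, a2, None, None)
                assert isinstance(cls, SelectivityClass)
                assert not flag

    def test_routing_rules(self):
        assert combine_two_step(0, 0, None, None)[0] == SelectivityClass.NONBINDER
        assert combine_two_step(1, 0, None, None)[0] == SelectivityClass.S1R_SELECTIVE
        assert combine_two_step(0, 1, None, None)[0] == SelectivityClass.S2R_SELECTIVE
        assert combine_two_step(1, 1, 1, 0)[0] == SelectivityClass.S1R_SELECTIVE
        assert combine_two_step(1, 1, 0, 1)[0] == SelectivityClass.S2R_SELECTIVE
        assert combine_two_step(1, 1, 0, 0)[0] == SelectivityClass.NONSELECTIVE
        cls, flag = combine_two_step(1, 1, 1, 1)
        assert cls == SelectivityClass.NONSELECTIVE and flag

    def test_end_to_end_with_oracle_models(self):
        smiles = ["A", "B", "C", "D"]
        act1 = _OracleModel({"A": 0, "B": 1, "C": 1, "D": 1}, "binary_activity")
        act2 = _OracleModel({"A": 0, "B": 0, "C": 1, "D": 1}, "binary_activity")
        sel1 = _OracleModel({"C": 1, "D": 0}, "binary_selectivity")
        sel2 = _OracleModel({"C": 0, "D": 0}, "binary_selectivity")
        preds = predict_two_step_classification(smiles, act1, act2, sel1, sel2)
        assert [p.predicted_class for p in preds] == [
            SelectivityClass.NONBINDER,
            SelectivityClass.S1R_SELECTIVE,
            SelectivityClass.S1R_SELECTIVE,
            SelectivityClass.NONSELECTIVE,
        ]
        # selectivity models are only consulted for both-active compounds
        assert preds[1].intermediate["selectivity_s1r"] is None


class TestTwoStepRegression:
    def test_examples(self):
        smiles = ["A", "B"]
        reg1 = _OracleModel({"A": 7.5, "B": 6.0}, "regression")
        reg2 = _OracleModel({"A": 5.2, "B": 5.5}, "regression")
        preds = predict_two_step_regression(smiles, reg1, reg2)
        assert preds[0].predicted_class == SelectivityClass.S1R_SELECTIVE
        assert preds[1].predicted_class == SelectivityClass.NONSELECTIVE
        assert preds[0].intermediate["pactivity_s1r"] == 7.5

    def test_oracle_regressors_reproduce_direct_labels_on_grid(self):
        """With perfect regressors the workflow equals direct labeling
        everywhere, including threshold boundaries."""
        grid = np.unique(np.concatenate([np.linspace(2, 10, 45), [5.0, 7.0]]))
        points = [(a, b) for a in grid for b in grid]
        smiles = [f"P{i}" for i in range(len(points))]
        reg1 = _OracleModel({s: p[0] for s, p in zip(smiles, points)}, "regression")
        reg2 = _OracleModel({s: p[1] for s, p in zip(smiles, points)}, "regression")
        preds = predict_two_step_regression(smiles, reg1, reg2)
        for pred, (a, b) in zip(preds, points):
            assert pred.predicted_class == selectivity_class(a, b)
            assert pred.predicted_class.value == brute_selectivity(a, b)


class TestOneStepMulticlass:
    def test_per_target_reporting_and_inconsistency_flag(self):
        smiles = ["A", "B"]
        m1 = _OracleModel({"A": 1, "B": 1}, "multiclass")
        m2 = _OracleModel({"A": 2, "B": 1}, "multiclass")
        preds = predict_one_step_multiclass(smiles, m1, m2)
        assert preds[0].multiclass_s1r == MulticlassLabel.SELECTIVE
        assert preds[0].multiclass_s2r == MulticlassLabel.NONSELECTIVE
        assert not preds[0].intermediate["inconsistent"]
        assert preds[1].intermediate["inconsistent"]  # both claim their target


class TestExternalReport:
    def test_perfect_predictions(self):
        y = np.array(["a"] * 10 + ["b"] * 5)
        rep = external_report(y, y, n_boot=200, seed=0)
        for cls in ("a", "b"):
            assert rep.per_class[cls]["f1"] == 1.0
            assert rep.per_class[cls]["f1_ci"] == (1.0, 1.0)
        assert rep.overall["accuracy"]["value"] == 1.0

    def test_confusion_arithmetic(self):
        """90 nonselective + 10 selective truth with 3 selective missed."""
        truth = np.array(["nonsel"] * 90 + ["sel"] * 10)
        pred = truth.copy()
        pred[90:93] = "nonsel"
        rep = external_report(pred, truth, n_boot=100, seed=0)
        sel = rep.per_class["sel"]
        assert sel["recall"] == pytest.approx(0.7)
        assert sel["precision"] == pytest.approx(1.0)
        assert sel["support"] == 10
        nonsel = rep.per_class["nonsel"]
        assert nonsel["precision"] == pytest.approx(90 / 93)
        assert rep.overall["accuracy"]["value"] == pytest.approx(0.97)

    def test_ci_contains_point_and_deterministic(self):
        rng = np.random.default_rng(0)
        truth = rng.choice(["x", "y", "z"], 80, p=[0.6, 0.3, 0.1])
        pred = np.where(rng.random(80) < 0.8, truth, rng.choice(["x", "y", "z"], 80))
        a = external_report(pred, truth, n_boot=300, seed=5)
        b = external_report(pred, truth, n_boot=300, seed=5)
        for cls, entry in a.per_class.items():
            if entry["support"]:
                for m in ("precision", "recall", "f1"):
                    lo, hi = entry[f"{m}_ci"]
                    assert lo <= entry[m] <= hi
            assert b.per_class[cls] == entry
        assert a.overall == b.overall

    def test_absent_class_flagged(self):
        truth = np.array(["a", "a", "b", "b"])
        pred = np.array(["a", "c", "b", "b"])
        rep = external_report(pred, truth, n_boot=50, seed=0)
        assert rep.per_class["c"]["support"] == 0
        assert rep.per_class["c"]["undefined"]

    def test_needs_two_classes(self):
        with pytest.raises(UsageError):
            external_report(["a", "a"], ["a", "a"], n_boot=10)
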