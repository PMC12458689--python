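"""The three prediction architectures and external-validation reporting.

* 2-step classification: per-target binary activity models gate per-target
  binary selectivity models; only compounds predicted active on both
  targets reach the selectivity stage, single-target actives are called
  selective for that target, double inactives are nonbinders.
* 2-step regression: per-target pActivity regressors, then the standard
  threshold rules (active > 5, selective at a 100-fold / 2-log-unit gap)
  applied to the predicted values.
* 1-step multiclass: one 3-class model per target
  (inactive / selective / nonselective); both calls are reported without
  forced reconciliation.

``external_report`` produces per-class precision/recall/F1 with percentile
bootstrap confidence intervals, plus overall accuracy, MCC and (when
scores are available) weighted ROC-AUC.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import accuracy_score, matthews_corrcoef, precision_recall_fscore_support

from .errors import CompatibilityError, UsageError
from .labeling import MulticlassLabel, SelectivityClass, selectivity_class
from .modeling import classification_metrics


class Workflow(str, Enum):
    TWO_STEP_CLASSIFICATION = "2-step classification"
    TWO_STEP_REGRESSION = "2-step regression"
    ONE_STEP_MULTICLASS = "1-step multiclass"


@dataclass
class WorkflowPrediction:
    canonical_smiles: str
    workflow: Workflow
    predicted_class: Optional[SelectivityClass]
    intermediate: dict = field(default_factory=dict)
    # per-target 3-class calls, populated by the multiclass workflow
    multiclass_s1r: Optional[MulticlassLabel] = None
    multiclass_s2r: Optional[MulticlassLabel] = None


def _check_task(model, expected: str) -> None:
    task = getattr(model, "task", None)
    if task is not None and str(getattr(task, "value", task)) != expected:
        raise CompatibilityError(f"model task {task} incompatible with expected {expected!r}")


def combine_two_step(a1: int, a2: int, s1: Optional[int], s2: Optional[int]) -> tuple[SelectivityClass, bool]:
    """Routing table of the 2-step classification workflow.

    ``a1``/``a2`` are per-target activity calls, ``s1``/``s2`` the
    selectivity-model calls (queried only when both targets are active).
    Returns (class, inconsistent-flag); total over all outcome combinations.
    """
    if not a1 and not a2:
        return SelectivityClass.NONBINDER, False
    if a1 and not a2:
        return SelectivityClass.S1R_SELECTIVE, False
    if a2 and not a1:
        return SelectivityClass.S2R_SELECTIVE, False
    if s1 and not s2:
        return SelectivityClass.S1R_SELECTIVE, False
    if s2 and not s1:
        return SelectivityClass.S2R_SELECTIVE, False
    if s1 and s2:
        # both selectivity models claim their own target: no defensible
        # single call exists, report nonselective and flag it
        return SelectivityClass.NONSELECTIVE, True
    return SelectivityClass.NONSELECTIVE, False


def predict_two_step_classification(
    smiles_list: Sequence[str],
    activity_model_s1r,
    activity_model_s2r,
    selectivity_model_s1r,
    selectivity_model_s2r,
) -> list[WorkflowPrediction]:
    for m in (activity_model_s1r, activity_model_s2r):
        _check_task(m, "binary_activity")
    for m in (selectivity_model_s1r, selectivity_model_s2r):
        _check_task(m, "binary_selectivity")

    smiles_list = list(smiles_list)
    a1 = np.asarray(activity_model_s1r.predict_smiles(smiles_list), dtype=int)
    a2 = np.asarray(activity_model_s2r.predict_smiles(smiles_list), dtype=int)
    both_idx = [i for i, (x1, x2) in enumerate(zip(a1, a2)) if x1 and x2]
    s1_map: dict[int, int] = {}
    s2_map: dict[int, int] = {}
    if both_idx:
        both_smiles = [smiles_list[i] for i in both_idx]
        s1_pred = np.asarray(selectivity_model_s1r.predict_smiles(both_smiles), dtype=int)
        s2_pred = np.asarray(selectivity_model_s2r.predict_smiles(both_smiles), dtype=int)
        s1_map = dict(zip(both_idx, s1_pred.tolist()))
        s2_map = dict(zip(both_idx, s2_pred.tolist()))

    out = []
    for i, (smi, x1, x2) in enumerate(zip(smiles_list, a1, a2)):
        s1 = s1_map.get(i)
        s2 = s2_map.get(i)
        cls, inconsistent = combine_two_step(int(x1), int(x2), s1, s2)
        out.append(
            WorkflowPrediction(
                canonical_smiles=smi,
                workflow=Workflow.TWO_STEP_CLASSIFICATION,
                predicted_class=cls,
                intermediate={
                    "activity_s1r": int(x1),
                    "activity_s2r": int(x2),
                    "selectivity_s1r": s1,
                    "selectivity_s2r": s2,
                    "inconsistent": inconsistent,
                },
            )
        )
    return out


def predict_two_step_regression(
    smiles_list: Sequence[str], regressor_s1r, regressor_s2r
) -> list[WorkflowPrediction]:
    _check_task(regressor_s1r, "regression")
    _check_task(regressor_s2r, "regression")
    smiles_list = list(smiles_list)
    p1 = np.asarray(regressor_s1r.predict_smiles(smiles_list), dtype=float)
    p2 = np.asarray(regressor_s2r.predict_smiles(smiles_list), dtype=float)
    return [
        WorkflowPrediction(
            canonical_smiles=smi,
            workflow=Workflow.TWO_STEP_REGRESSION,
            predicted_class=selectivity_class(float(a), float(b)),
            intermediate={"pactivity_s1r": float(a), "pactivity_s2r": float(b)},
        )
        for smi, a, b in zip(smiles_list, p1, p2)
    ]


def predict_one_step_multiclass(
    smiles_list: Sequence[str], multiclass_model_s1r, multiclass_model_s2r
) -> list[WorkflowPrediction]:
    _check_task(multiclass_model_s1r, "multiclass")
    _check_task(multiclass_model_s2r, "multiclass")
    smiles_list = list(smiles_list)
    m1 = np.asarray(multiclass_model_s1r.predict_smiles(smiles_list), dtype=int)
    m2 = np.asarray(multiclass_model_s2r.predict_smiles(smiles_list), dtype=int)
    out = []
    for smi, c1, c2 in zip(smiles_list, m1, m2):
        l1, l2 = MulticlassLabel(int(c1)), MulticlassLabel(int(c2))
        inconsistent = l1 == MulticlassLabel.SELECTIVE and l2 == MulticlassLabel.SELECTIVE
        out.append(
            WorkflowPrediction(
                canonical_smiles=smi,
                workflow=Workflow.ONE_STEP_MULTICLASS,
                predicted_class=None,
                multiclass_s1r=l1,
                multiclass_s2r=l2,
                intermediate={"s1r": int(c1), "s2r": int(c2), "inconsistent": bool(inconsistent)},
            )
        )
    return out


# ---------------------------------------------------------------------------
# External-validation reporting


@dataclass
class ClassReport:
    per_class: dict
    overall: dict
    n: int
    n_boot: int
    seed: int


def _per_class_metrics(y_true, y_pred, classes) -> dict:
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    return {
        c: {"precision": prec[i], "recall": rec[i], "f1": f1[i], "support": int(support[i])}
        for i, c in enumerate(classes)
    }


def external_report(
    predictions: Sequence,
    truth: Sequence,
    y_score=None,
    classes: Optional[Sequence] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassReport:
    """Per-class classification report with 95% percentile bootstrap CIs.

    Bootstrap resampling is at compound level under the given seed.
    Classes absent from the truth are reported with support 0 and their
    undefined metrics flagged as NaN.
    """
    y_true = np.asarray(truth)
    y_pred = np.asarray(predictions)
    if len(y_true) != len(y_pred):
        raise UsageError("predictions and truth must align")
    if len(np.unique(y_true)) < 2:
        raise UsageError("external report needs at least two classes in the truth")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    classes = list(classes)

    point = _per_class_metrics(y_true, y_pred, classes)
    overall_point = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
    }
    if y_score is not None:
        overall_point["roc_auc"] = classification_metrics(
            y_true, y_pred, y_score, labels=np.asarray(classes)
        )["ROC_AUC"]

    import warnings

    rng = np.random.default_rng(seed)
    n = len(y_true)
    boot_pc = {c: {m: [] for m in ("precision", "recall", "f1")} for c in classes}
    boot_overall = {k: [] for k in overall_point}
    score_arr = None if y_score is None else np.asarray(y_score)
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="A single label was found", category=UserWarning
        )
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            yt, yp = y_true[idx], y_pred[idx]
            pc = _per_class_metrics(yt, yp, classes)
            for c in classes:
                present = pc[c]["support"] > 0
                for m in ("precision", "recall", "f1"):
                    boot_pc[c][m].append(pc[c][m] if present else np.nan)
            boot_overall["accuracy"].append(accuracy_score(yt, yp))
            boot_overall["mcc"].append(matthews_corrcoef(yt, yp))
            if score_arr is not None:
                try:
                    boot_overall["roc_auc"].append(
                        classification_metrics(
                            yt, yp, score_arr[idx], labels=np.asarray(classes)
                        )["ROC_AUC"]
                    )
                except ValueError:
                    boot_overall["roc_auc"].append(np.nan)

    per_class = {}
    for c in classes:
        entry = dict(point[c])
        entry["undefined"] = point[c]["support"] == 0
        for m in ("precision", "recall", "f1"):
            vals = np.asarray(boot_pc[c][m], dtype=float)
            if entry["undefined"] or np.all(np.isnan(vals)):
                entry[f"{m}_ci"] = (float("nan"), float("nan"))
            else:
                lo, hi = np.nanpercentile(vals, [2.5, 97.5])
                entry[f"{m}_ci"] = (float(min(lo, entry[m])), float(max(hi, entry[m])))
        per_class[c] = entry

    overall = {}
    for k, v in overall_point.items():
        vals = np.asarray(boot_overall[k], dtype=float)
        lo, hi = np.nanpercentile(vals, [2.5, 97.5])
        overall[k] = {"value": float(v), "ci": (float(min(lo, v)), float(max(hi, v)))}

    return ClassReport(per_class=per_class, overall=overall, n=n, n_boot=n_boot, seed=seed)
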