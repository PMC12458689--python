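"""End-to-end study orchestration.

``run_study`` executes the whole protocol on a raw bioactivity table:
curation -> labeling -> external split -> six datasets -> representation x
algorithm sweep under nested CV -> winner freeze -> classical CV ->
final models -> external validation of the three workflow architectures,
with every random draw derived from one seed. Winners are picked per task
by mean outer-fold optimization metric, standard deviation breaking ties;
an explicit (algorithm, representation) pin per task overrides the
automatic choice.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .curation import CompoundProfile, RawActivityRecord, curate
from .datasets import LabeledDataset, SplitResult, Task, build_dataset, extract_external_set
from .errors import UsageError
from .featurization import FeatureMatrix, RepresentationKind, compute_representation
from .labeling import MulticlassLabel, SelectivityClass, profile_selectivity
from .modeling import (
    Algorithm,
    FittedModel,
    ModelConfig,
    classical_cv,
    default_search_space,
    freeze_hyperparameters,
    nested_cv,
    optimization_metric,
    train_final_model,
)
from .workflows import (
    Workflow,
    external_report,
    predict_one_step_multiclass,
    predict_two_step_classification,
    predict_two_step_regression,
)

#: study tasks -> (dataset id, regression flag)
TASKS = {
    "activity_s1r": (1, False),
    "activity_s2r": (2, False),
    "selectivity_s1r": (3, False),
    "selectivity_s2r": (4, False),
    "multiclass_s1r": (5, False),
    "multiclass_s2r": (6, False),
    "regression_s1r": (1, True),
    "regression_s2r": (2, True),
}


@dataclass
class RunConfig:
    seed: int = 0
    external_fraction: float = 0.10
    representations: Sequence[RepresentationKind] = field(
        default_factory=lambda: list(RepresentationKind)
    )
    algorithms: Sequence[Algorithm] = field(default_factory=lambda: list(Algorithm))
    n_trials: int = 50
    n_outer: int = 5
    n_inner: int = 5
    classical_trials: int = 25
    n_boot: int = 2000
    outdir: Optional[str] = None
    #: manual winner override: task name -> (Algorithm, RepresentationKind)
    pins: dict = field(default_factory=dict)
    #: per-algorithm search-space override (e.g. scaled-down ranges)
    search_spaces: dict = field(default_factory=dict)
    tasks: Sequence[str] = field(default_factory=lambda: list(TASKS))


class _FeatureCache:
    """One representation computation per (kind, compound set)."""

    def __init__(self, smiles: Sequence[str]):
        self.smiles = list(smiles)
        self.index = {s: i for i, s in enumerate(self.smiles)}
        self._full: dict[RepresentationKind, FeatureMatrix] = {}

    def matrix(self, kind: RepresentationKind, smiles: Sequence[str]) -> FeatureMatrix:
        kind = RepresentationKind(kind)
        if kind not in self._full:
            self._full[kind] = compute_representation(self.smiles, kind)
        rows = [self.index[s] for s in smiles]
        return self._full[kind].rows(rows)


def _to_multiclass_frame(cls: SelectivityClass, target: str) -> int:
    own = SelectivityClass.S1R_SELECTIVE if target == "s1r" else SelectivityClass.S2R_SELECTIVE
    if cls == own:
        return int(MulticlassLabel.SELECTIVE)
    if cls == SelectivityClass.NONBINDER:
        return int(MulticlassLabel.INACTIVE)
    return int(MulticlassLabel.NONSELECTIVE)


def workflow_to_per_target(pred, target: str) -> int:
    """Map a workflow prediction into the per-target 3-class frame."""
    if pred.workflow == Workflow.ONE_STEP_MULTICLASS:
        return int(pred.multiclass_s1r if target == "s1r" else pred.multiclass_s2r)
    return _to_multiclass_frame(pred.predicted_class, target)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value") and not isinstance(obj, (int, float)):
        return obj.value
    return obj


def _external_hash(external: Sequence[CompoundProfile]) -> str:
    data = "\n".join(sorted(p.canonical_smiles for p in external))
    return hashlib.sha256(data.encode()).hexdigest()


def run_study(records: Sequence[RawActivityRecord], config: RunConfig) -> dict:
    """Execute the full study; returns a JSON-serializable report."""
    report: dict = {"seed": config.seed}

    curation = curate(records)
    report["curation_log"] = curation.log.to_dict()

    split = extract_external_set(
        curation.profiles, fraction=config.external_fraction, seed=config.seed
    )
    report["external"] = {
        "n": len(split.external),
        "per_class": split.per_class_external,
        "hash": _external_hash(split.external),
    }

    datasets: dict[str, LabeledDataset] = {}
    for task_name in config.tasks:
        ds_id, regression = TASKS[task_name]
        datasets[task_name] = build_dataset(ds_id, split.training, regression=regression)
    report["dataset_sizes"] = {k: len(v) for k, v in datasets.items()}

    train_smiles = sorted({s for ds in datasets.values() for s in ds.smiles})
    cache = _FeatureCache(train_smiles)

    # --- nested-CV sweep and winner selection
    sweep: dict = {}
    winners: dict = {}
    for task_name, ds in datasets.items():
        metric = optimization_metric(ds.task)
        maximize = metric != "RMSE"
        cells = {}
        for kind in config.representations:
            kind = RepresentationKind(kind)
            fm = cache.matrix(kind, ds.smiles)
            for algo in config.algorithms:
                algo = Algorithm(algo)
                mc = ModelConfig(
                    algorithm=algo,
                    task=ds.task,
                    search_space=config.search_spaces.get(algo),
                    seed=config.seed,
                )
                key = f"{algo.value}|{kind.value}"
                try:
                    cv = nested_cv(
                        ds, fm, mc,
                        n_outer=config.n_outer,
                        n_inner=config.n_inner,
                        n_trials=config.n_trials,
                    )
                except Exception as exc:  # cell failure: log and continue
                    cells[key] = {"failed": True, "error": f"{type(exc).__name__}: {exc}"}
                    continue
                cells[key] = {
                    "failed": False,
                    "mean": cv.mean,
                    "sd": cv.sd,
                    "best_params_per_fold": cv.best_params_per_fold,
                }
        sweep[task_name] = cells

        if task_name in config.pins:
            algo, kind = config.pins[task_name]
            win_key = f"{Algorithm(algo).value}|{RepresentationKind(kind).value}"
        else:
            ok = {k: v for k, v in cells.items() if not v["failed"]}
            if not ok:
                raise UsageError(f"every sweep cell failed for task {task_name}")
            sign = -1.0 if maximize else 1.0
            win_key = min(ok, key=lambda k: (sign * ok[k]["mean"][metric], ok[k]["sd"][metric]))
        winners[task_name] = win_key
    report["sweep"] = sweep
    report["winners"] = winners

    # --- freeze, classical CV, final models
    classical: dict = {}
    finals: dict[str, FittedModel] = {}
    for task_name, ds in datasets.items():
        algo_v, kind_v = winners[task_name].split("|")
        algo, kind = Algorithm(algo_v), RepresentationKind(kind_v)
        cell = sweep[task_name][winners[task_name]]
        space = dict(config.search_spaces.get(algo) or default_search_space(algo, ds.task))
        fixed, narrowed = freeze_hyperparameters(cell["best_params_per_fold"], space)
        space.update(narrowed)
        mc = ModelConfig(algorithm=algo, task=ds.task, search_space=space,
                         fixed_params=fixed, seed=config.seed)
        fm = cache.matrix(kind, ds.smiles)
        cv = classical_cv(ds, fm, mc, n_trials=config.classical_trials)
        classical[task_name] = {
            "algorithm": algo.value,
            "representation": kind.value,
            "fixed_params": _jsonable(fixed),
            "tuned_params": _jsonable(cv.diagnostics["tuned_params"]),
            "narrowed_space": cv.diagnostics["narrowed_space"],
            "mean": cv.mean,
            "sd": cv.sd,
        }
        final_params = {**fixed, **cv.diagnostics["tuned_params"]}
        finals[task_name] = train_final_model(
            ds, kind,
            ModelConfig(algorithm=algo, task=ds.task, search_space=space,
                        fixed_params=final_params, seed=config.seed),
            features=fm,
        )
    report["classical_cv"] = classical

    # --- external validation of the three workflows
    ext_smiles = [p.canonical_smiles for p in split.external]
    truth_cls = [profile_selectivity(p) for p in split.external]
    truth = {
        "s1r": np.array([_to_multiclass_frame(c, "s1r") for c in truth_cls]),
        "s2r": np.array([_to_multiclass_frame(c, "s2r") for c in truth_cls]),
    }

    wf_preds = {
        Workflow.TWO_STEP_CLASSIFICATION: predict_two_step_classification(
            ext_smiles,
            finals["activity_s1r"], finals["activity_s2r"],
            finals["selectivity_s1r"], finals["selectivity_s2r"],
        ),
        Workflow.TWO_STEP_REGRESSION: predict_two_step_regression(
            ext_smiles, finals["regression_s1r"], finals["regression_s2r"]
        ),
        Workflow.ONE_STEP_MULTICLASS: predict_one_step_multiclass(
            ext_smiles, finals["multiclass_s1r"], finals["multiclass_s2r"]
        ),
    }

    comparison: dict = {}
    for wf, preds in wf_preds.items():
        entry: dict = {}
        mccs = []
        for target in ("s1r", "s2r"):
            y_pred = np.array([workflow_to_per_target(p, target) for p in preds])
            rep = external_report(
                y_pred, truth[target], n_boot=config.n_boot, seed=config.seed
            )
            entry[target] = {
                "per_class": _jsonable(rep.per_class),
                "overall": _jsonable(rep.overall),
            }
            mccs.append(rep.overall["mcc"]["value"])
        entry["mean_mcc"] = float(np.mean(mccs))
        comparison[wf.value] = entry
    ranking = sorted(comparison, key=lambda k: -comparison[k]["mean_mcc"])
    report["workflow_comparison"] = comparison
    report["workflow_ranking"] = ranking

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for task_name, model in finals.items():
            model.save(outdir / "models" / task_name)
        (outdir / "manifest.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
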