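"""Model selection and evaluation: nested and classical 5-fold CV.

Five algorithm families (random forest, extra trees, gradient-boosted
trees, SVM, kNN) are tuned by a tree-structured Parzen estimator search
(50 trials by default) inside a nested cross-validation: 5 outer folds
estimate generalization, 5 inner folds drive the hyperparameter search,
maximizing weighted ROC-AUC for classification or minimizing RMSE for
regression. Severely imbalanced classification datasets (the selectivity
and multiclass tasks) are randomly undersampled to the minority-class
count inside every training portion; test folds keep the original
imbalance. Feature selection and scaling are re-fitted inside each
training portion so no test-fold statistic ever leaks into a fit.

Margin- and distance-based algorithms (SVM, kNN) receive standardized
features (scaler fitted on the training portion); tree ensembles receive
raw features.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    matthews_corrcoef,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.class_weight import compute_sample_weight
from xgboost import XGBClassifier, XGBRegressor

from . import tpe
from .datasets import LabeledDataset, Task
from .errors import CompatibilityError, StructureError, UndefinedError, UsageError
from .featurization import FeatureMatrix, RepresentationKind, compute_representation, select_features

__version_stamp__ = "sigsel-model-1"

#: datasets with severe class imbalance, undersampled during training
IMBALANCED_DATASETS = {3, 4, 5, 6}


class Algorithm(str, Enum):
    RANDOM_FOREST = "rf"
    EXTRA_TREES = "et"
    GRADIENT_BOOSTED_TREES = "xgboost"
    SVM = "svm"
    KNN = "knn"


def default_search_space(algorithm: Algorithm, task: Task) -> dict:
    """Published hyperparameter search space per algorithm, split by task."""
    regression = task == Task.REGRESSION
    if algorithm in (Algorithm.EXTRA_TREES, Algorithm.RANDOM_FOREST):
        rf = algorithm == Algorithm.RANDOM_FOREST
        space = {
            "bootstrap": tpe.Categorical([True, False]),
            "max_features": tpe.Categorical(["sqrt", "log2"]),
            "n_estimators": tpe.Int(100, 1500 if rf else 1000),
            "max_depth": tpe.Int(5, 80) if rf else tpe.Int(3, 30),
            "min_samples_split": tpe.Int(2, 20),
            "min_samples_leaf": tpe.Int(1, 6) if rf else tpe.Int(1, 10),
        }
        if regression:
            space["criterion"] = tpe.Categorical(
                ["squared_error", "absolute_error", "friedman_mse", "poisson"]
            )
        else:
            space["criterion"] = tpe.Categorical(["gini", "entropy"])
            space["class_weight"] = tpe.Categorical(["balanced", "balanced_subsample"])
        return space
    if algorithm == Algorithm.GRADIENT_BOOSTED_TREES:
        return {
            "n_estimators": tpe.Int(10, 1000),
            "max_depth": tpe.Int(3, 30),
            "learning_rate": tpe.Float(0.01, 0.3, log=True),
            "subsample": tpe.Float(0.5, 1.0),
            "colsample_bytree": tpe.Float(0.5, 1.0),
        }
    if algorithm == Algorithm.SVM:
        space = {
            "C": tpe.Float(0.01, 100.0, log=True),
            "gamma": tpe.Float(1e-4, 1.0, log=True),
        }
        if regression:
            space["epsilon"] = tpe.Float(0.01, 1.0)
        return space
    if algorithm == Algorithm.KNN:
        return {
            "n_neighbors": tpe.Int(2, 30),
            "weights": tpe.Categorical(["distance", "uniform"]),
            "metric": tpe.Categorical(["minkowski", "euclidean", "manhattan"]),
            "leaf_size": tpe.Int(1, 50),
        }
    raise UsageError(f"unknown algorithm {algorithm}")


@dataclass
class ModelConfig:
    algorithm: Algorithm
    task: Task
    search_space: Optional[dict] = None
    fixed_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithm = Algorithm(self.algorithm)
        if self.search_space is None:
            self.search_space = default_search_space(self.algorithm, self.task)
        allowed = set(default_search_space(self.algorithm, self.task))
        unknown = set(self.search_space) - allowed
        if unknown:
            raise UsageError(f"search-space keys outside the published space: {sorted(unknown)}")


@dataclass
class CVResult:
    per_fold: list[dict]
    mean: dict
    sd: dict
    best_params_per_fold: list[dict]
    diagnostics: dict = field(default_factory=dict)


def _summarize(per_fold: list[dict]) -> tuple[dict, dict]:
    keys = per_fold[0].keys()
    mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
    sd = {k: float(np.std([f[k] for f in per_fold], ddof=1)) if len(per_fold) > 1 else 0.0 for k in keys}
    return mean, sd


def build_estimator(algorithm: Algorithm, task: Task, params: dict, seed: int):
    """Instantiate an estimator for (algorithm, task) with the given
    hyperparameters; SVM and kNN are wrapped in a standardizing pipeline."""
    regression = task == Task.REGRESSION
    p = dict(params)
    if algorithm in (Algorithm.EXTRA_TREES, Algorithm.RANDOM_FOREST):
        cls = {
            (Algorithm.EXTRA_TREES, False): ExtraTreesClassifier,
            (Algorithm.EXTRA_TREES, True): ExtraTreesRegressor,
            (Algorithm.RANDOM_FOREST, False): RandomForestClassifier,
            (Algorithm.RANDOM_FOREST, True): RandomForestRegressor,
        }[(algorithm, regression)]
        return cls(random_state=seed, n_jobs=1, **p)
    if algorithm == Algorithm.GRADIENT_BOOSTED_TREES:
        cls = XGBRegressor if regression else XGBClassifier
        return cls(random_state=seed, n_jobs=1, verbosity=0, **p)
    if algorithm == Algorithm.SVM:
        if regression:
            est = SVR(kernel="rbf", **p)
        else:
            est = SVC(kernel="rbf", class_weight="balanced", random_state=seed, **p)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if algorithm == Algorithm.KNN:
        cls = KNeighborsRegressor if regression else KNeighborsClassifier
        return Pipeline([("scale", StandardScaler()), ("model", cls(**p))])
    raise UsageError(f"unknown algorithm {algorithm}")


def _fit(est, X, y, algorithm: Algorithm, task: Task):
    if algorithm == Algorithm.GRADIENT_BOOSTED_TREES and task != Task.REGRESSION:
        est.fit(X, y, sample_weight=compute_sample_weight("balanced", y))
    else:
        est.fit(X, y)
    return est


def prediction_scores(est, X, task: Task) -> np.ndarray:
    """Class scores for ROC-AUC: probabilities when available, otherwise
    decision-function margins (monotone-equivalent for AUC)."""
    model = est
    if hasattr(est, "named_steps"):
        model = est.named_steps["model"]
    if hasattr(model, "predict_proba"):
        proba = est.predict_proba(X)
        return proba[:, 1] if proba.shape[1] == 2 else proba
    return est.decision_function(X)


# ---------------------------------------------------------------------------
# Metrics


def classification_metrics(y_true, y_pred, y_score, labels=None, include_auc: bool = True) -> dict:
    """Weighted-average F1/precision/recall, MCC, and (unless disabled)
    ROC-AUC, one-vs-rest support-weighted for multiclass."""
    if y_score is None and include_auc:
        raise UsageError("y_score is required for ROC-AUC")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise UsageError("y_true and y_pred must have equal length")
    if labels is None:
        labels = np.unique(y_true)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0
    )
    out = {
        "F1": float(f1),
        "PRECISION": float(prec),
        "RECALL": float(rec),
        "MCC": float(matthews_corrcoef(y_true, y_pred)),
    }
    if include_auc:
        score = np.asarray(y_score)
        if score.ndim == 2 and score.shape[1] == 2:
            score = score[:, 1]
        if score.ndim == 1:
            auc = roc_auc_score(y_true, score)
        else:
            # weighted one-vs-rest AUC, valid for margins as well as
            # probabilities (per-class column ordering is all that matters)
            aucs, weights = [], []
            for j, c in enumerate(labels):
                mask = y_true == c
                aucs.append(roc_auc_score(mask, score[:, j]))
                weights.append(mask.sum())
            auc = float(np.average(aucs, weights=weights))
        out["ROC_AUC"] = float(auc)
    return out


def regression_metrics(y_true, y_pred) -> dict:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise UsageError("y_true and y_pred must be equal-length and non-empty")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedError("R^2 undefined for zero-variance y_true")
    r2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot
    return {"RMSE": rmse, "R2": r2}


# ---------------------------------------------------------------------------
# Imbalance handling


def undersample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a random undersample balancing every class to the
    minority count; sorted for determinism of downstream fits."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# Cross-validation engines


def _check_inputs(dataset: LabeledDataset, features: FeatureMatrix, n_folds: int):
    if len(dataset) != features.values.shape[0]:
        raise UsageError("dataset rows and feature rows must align")
    if dataset.task != Task.REGRESSION:
        classes, counts = np.unique(dataset.y, return_counts=True)
        if len(classes) < 2:
            raise UsageError("classification needs at least two classes")
        if counts.min() < n_folds:
            raise UsageError(
                f"every class needs >= {n_folds} members for {n_folds}-fold CV"
            )


def _should_undersample(dataset: LabeledDataset, undersample: Optional[bool]) -> bool:
    if undersample is not None:
        return undersample
    return dataset.task != Task.REGRESSION and dataset.dataset_id in IMBALANCED_DATASETS


def _should_select(features: FeatureMatrix, select) -> bool:
    if select == "auto":
        return not features.kind.is_fingerprint
    return bool(select)


def _splitter(task: Task, n_folds: int, seed: int):
    if task == Task.REGRESSION:
        return KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)


def _prepare_fold(X, y, tr_idx, do_select, do_undersample, rng):
    """Per-fold training-side preprocessing: selection fitted on the
    training rows only, then optional undersampling of those rows."""
    if do_select:
        sub = FeatureMatrix(X[tr_idx], [str(i) for i in range(X.shape[1])], RepresentationKind.DESC_COMPACT_2D)
        retained, _ = select_features(sub)
    else:
        retained = np.arange(X.shape[1])
    fit_idx = tr_idx
    if do_undersample:
        local = undersample_indices(y[tr_idx], rng)
        fit_idx = tr_idx[local]
    return retained, fit_idx


def _eval_fold(est, X, y, te_idx, retained, task: Task, labels) -> dict:
    Xte = X[np.ix_(te_idx, retained)]
    if task == Task.REGRESSION:
        return regression_metrics(y[te_idx], est.predict(Xte))
    return classification_metrics(
        y[te_idx], est.predict(Xte), prediction_scores(est, Xte, task), labels=labels
    )


_OPT_METRIC = {Task.REGRESSION: "RMSE"}  # classification tasks use ROC_AUC


def optimization_metric(task: Task) -> str:
    return _OPT_METRIC.get(task, "ROC_AUC")


def nested_cv(
    dataset: LabeledDataset,
    features: FeatureMatrix,
    config: ModelConfig,
    n_outer: int = 5,
    n_inner: int = 5,
    n_trials: int = 50,
    undersample: Optional[bool] = None,
    select: object = "auto",
) -> CVResult:
    """Nested cross-validation with an inner TPE hyperparameter search.

    The outer loop estimates generalization on held-out folds never seen by
    the search; the inner loop scores each trial's parameters by the mean
    optimization metric over 5 inner folds of the outer-training portion.
    """
    _check_inputs(dataset, features, n_outer)
    X = features.values
    y = dataset.y
    labels = None if dataset.task == Task.REGRESSION else np.unique(y)
    do_us = _should_undersample(dataset, undersample)
    do_sel = _should_select(features, select)
    metric = optimization_metric(dataset.task)
    sign = 1.0 if metric == "RMSE" else -1.0  # TPE minimizes

    outer = _splitter(dataset.task, n_outer, config.seed)
    per_fold: list[dict] = []
    best_params: list[dict] = []
    diag: dict = {"outer_folds": [], "retained_outer": [], "fit_class_counts": [], "scaler_mean": []}

    for fold_no, (tr_idx, te_idx) in enumerate(outer.split(X, None if labels is None else y)):
        fold_seed = config.seed * 1000 + fold_no
        rng = np.random.default_rng(fold_seed)
        inner = _splitter(dataset.task, n_inner, fold_seed + 1)
        inner_folds = []
        for itr, ite in inner.split(X[tr_idx], None if labels is None else y[tr_idx]):
            itr_g, ite_g = tr_idx[itr], tr_idx[ite]
            retained_i, fit_i = _prepare_fold(X, y, itr_g, do_sel, do_us, rng)
            inner_folds.append((fit_i, ite_g, retained_i))

        def objective(params: dict) -> float:
            vals = []
            for fit_i, ite_g, retained_i in inner_folds:
                est = build_estimator(
                    config.algorithm, dataset.task, {**config.fixed_params, **params}, fold_seed
                )
                _fit(est, X[np.ix_(fit_i, retained_i)], y[fit_i], config.algorithm, dataset.task)
                m = _eval_fold(est, X, y, ite_g, retained_i, dataset.task, labels)
                vals.append(m[metric])
            return sign * float(np.mean(vals))

        result = tpe.minimize(objective, config.search_space, n_trials=n_trials, seed=fold_seed)
        best = {**config.fixed_params, **result.best_params}
        best_params.append(result.best_params)

        retained_o, fit_o = _prepare_fold(X, y, tr_idx, do_sel, do_us, rng)
        est = build_estimator(config.algorithm, dataset.task, best, fold_seed)
        _fit(est, X[np.ix_(fit_o, retained_o)], y[fit_o], config.algorithm, dataset.task)
        per_fold.append(_eval_fold(est, X, y, te_idx, retained_o, dataset.task, labels))

        diag["outer_folds"].append((tr_idx.tolist(), te_idx.tolist()))
        diag["retained_outer"].append(retained_o.tolist())
        if dataset.task != Task.REGRESSION:
            cls, cnt = np.unique(y[fit_o], return_counts=True)
            diag["fit_class_counts"].append(dict(zip(cls.tolist(), cnt.tolist())))
        if hasattr(est, "named_steps"):
            diag["scaler_mean"].append(est.named_steps["scale"].mean_.tolist())

    mean, sd = _summarize(per_fold)
    return CVResult(per_fold, mean, sd, best_params, diag)


def freeze_hyperparameters(
    best_params_per_fold: Sequence[dict], space: dict
) -> tuple[dict, dict]:
    """Operationalize the freeze-then-narrow protocol after nested CV.

    Categorical parameters freeze at the modal value when it wins a
    majority (>= 3/5 folds); numeric parameters freeze at the median of
    fold-best values when all lie within +-25% of that median. Parameters
    that stay inconsistent get a narrowed range [min, max] of fold bests.
    When no parameter meets the consistency rules, the single most
    fold-consistent one is frozen anyway (at its mode or median) so the
    freeze-then-narrow protocol stays defined.
    """
    fixed: dict = {}
    narrowed: dict = {}
    n = len(best_params_per_fold)
    for name, spec in space.items():
        vals = [p[name] for p in best_params_per_fold]
        if isinstance(spec, tpe.Categorical):
            counts = {c: vals.count(c) for c in set(vals)}
            mode, cnt = max(counts.items(), key=lambda kv: kv[1])
            if cnt >= max(3, (n // 2) + 1):
                fixed[name] = mode
            else:
                narrowed[name] = tpe.Categorical(sorted(set(vals), key=str))
            continue
        arr = np.array(vals, dtype=float)
        med = float(np.median(arr))
        tol = 0.25 * abs(med)
        if med != 0 and np.all(np.abs(arr - med) <= tol):
            fixed[name] = int(round(med)) if isinstance(spec, tpe.Int) else med
        else:
            lo, hi = float(arr.min()), float(arr.max())
            if isinstance(spec, tpe.Int):
                lo_i, hi_i = int(round(lo)), int(round(hi))
                if lo_i == hi_i:
                    fixed[name] = lo_i
                else:
                    narrowed[name] = tpe.Int(lo_i, hi_i)
            else:
                if lo == hi:
                    fixed[name] = lo
                else:
                    narrowed[name] = tpe.Float(lo, hi, log=getattr(spec, "log", False))
    if not fixed:
        scores = {}
        for name, spec in space.items():
            vals = [p[name] for p in best_params_per_fold]
            if isinstance(spec, tpe.Categorical):
                scores[name] = 1.0 - max(vals.count(c) for c in set(vals)) / len(vals)
            else:
                arr = np.asarray(vals, dtype=float)
                med = float(np.median(arr))
                scale = abs(med) if med else (float(np.abs(arr).max()) or 1.0)
                scores[name] = float(np.abs(arr - med).max() / scale)
        chosen = min(sorted(scores), key=lambda k: scores[k])
        vals = [p[chosen] for p in best_params_per_fold]
        if isinstance(space[chosen], tpe.Categorical):
            fixed[chosen] = max(set(vals), key=lambda c: (vals.count(c), str(c)))
        else:
            med = float(np.median(np.asarray(vals, dtype=float)))
            fixed[chosen] = int(round(med)) if isinstance(space[chosen], tpe.Int) else med
        narrowed.pop(chosen, None)
    return fixed, narrowed


def classical_cv(
    dataset: LabeledDataset,
    features: FeatureMatrix,
    config: ModelConfig,
    n_folds: int = 5,
    n_trials: int = 25,
    undersample: Optional[bool] = None,
    select: object = "auto",
) -> CVResult:
    """Single-level 5-fold CV with hyperparameters frozen after nested CV.

    Any parameters in the (narrowed) search space that are not fixed are
    tuned once, by TPE over the mean fold metric; with a fully fixed
    configuration, exactly ``n_folds`` fits happen.
    """
    if not config.fixed_params:
        raise UsageError("classical_cv requires non-empty fixed_params")
    _check_inputs(dataset, features, n_folds)
    X, y = features.values, dataset.y
    labels = None if dataset.task == Task.REGRESSION else np.unique(y)
    do_us = _should_undersample(dataset, undersample)
    do_sel = _should_select(features, select)
    metric = optimization_metric(dataset.task)
    sign = 1.0 if metric == "RMSE" else -1.0

    splitter = _splitter(dataset.task, n_folds, config.seed)
    rng = np.random.default_rng(config.seed)
    folds = []
    for tr_idx, te_idx in splitter.split(X, None if labels is None else y):
        retained, fit_idx = _prepare_fold(X, y, tr_idx, do_sel, do_us, rng)
        folds.append((tr_idx, te_idx, retained, fit_idx))

    tunable = {k: v for k, v in config.search_space.items() if k not in config.fixed_params}

    def run(params: dict) -> list[dict]:
        out = []
        for _, te_idx, retained, fit_idx in folds:
            est = build_estimator(
                config.algorithm, dataset.task, {**config.fixed_params, **params}, config.seed
            )
            _fit(est, X[np.ix_(fit_idx, retained)], y[fit_idx], config.algorithm, dataset.task)
            out.append(_eval_fold(est, X, y, te_idx, retained, dataset.task, labels))
        return out

    chosen: dict = {}
    if tunable:
        result = tpe.minimize(
            lambda p: sign * float(np.mean([m[metric] for m in run(p)])),
            tunable,
            n_trials=n_trials,
            seed=config.seed,
        )
        chosen = result.best_params
    per_fold = run(chosen)
    mean, sd = _summarize(per_fold)
    diag = {
        "folds": [(tr.tolist(), te.tolist()) for tr, te, _, _ in folds],
        "retained": [r.tolist() for _, _, r, _ in folds],
        "fit_indices": [f.tolist() for _, _, _, f in folds],
        "tuned_params": chosen,
        "narrowed_space": {k: repr(v) for k, v in tunable.items()},
    }
    return CVResult(per_fold, mean, sd, [{**config.fixed_params, **chosen}] * n_folds, diag)


# ---------------------------------------------------------------------------
# Baselines


def run_baselines(
    dataset: LabeledDataset,
    features: FeatureMatrix,
    seed: int = 0,
    n_folds: int = 5,
) -> dict:
    """The paper-style baseline battery under plain (stratified) 5-fold CV.

    Classification: logistic regression, 1-NN, decision tree, logistic
    regression on the SLogP descriptor alone, majority-class dummy, and
    uniform-random dummy. Regression: a training-median dummy.
    Returns {baseline name: CVResult}.
    """
    _check_inputs(dataset, features, n_folds)
    X, y = features.values, dataset.y
    out: dict[str, CVResult] = {}

    if dataset.task == Task.REGRESSION:
        models = {"median_dummy": DummyRegressor(strategy="median")}
    else:
        models = {
            "logistic_regression": Pipeline(
                [("scale", StandardScaler()), ("model", LogisticRegression(max_iter=2000, random_state=seed))]
            ),
            "1nn": Pipeline(
                [("scale", StandardScaler()), ("model", KNeighborsClassifier(n_neighbors=1))]
            ),
            "decision_tree": DecisionTreeClassifier(random_state=seed),
            "majority_dummy": DummyClassifier(strategy="most_frequent"),
            "uniform_dummy": DummyClassifier(strategy="uniform", random_state=seed),
        }
        slogp_cols = [i for i, n in enumerate(features.names) if n in ("MolLogP", "SLogP")]
        if slogp_cols:
            models["logreg_slogp"] = Pipeline(
                [("scale", StandardScaler()), ("model", LogisticRegression(max_iter=2000, random_state=seed))]
            )

    labels = None if dataset.task == Task.REGRESSION else np.unique(y)
    splitter = _splitter(dataset.task, n_folds, seed)
    clean = np.flatnonzero(~np.isnan(X).any(axis=0))
    if clean.size == 0:
        clean = np.arange(X.shape[1])
        X = np.nan_to_num(X, nan=0.0)
    for name, est in models.items():
        cols = np.array(slogp_cols[:1]) if name == "logreg_slogp" else clean
        per_fold = []
        for tr_idx, te_idx in splitter.split(X, None if labels is None else y):
            from sklearn.base import clone

            model = clone(est)
            model.fit(X[np.ix_(tr_idx, cols)], y[tr_idx])
            Xte = X[np.ix_(te_idx, cols)]
            if dataset.task == Task.REGRESSION:
                per_fold.append(regression_metrics(y[te_idx], model.predict(Xte)))
            else:
                score = model.predict_proba(Xte)
                score = score[:, 1] if score.shape[1] == 2 else score
                per_fold.append(
                    classification_metrics(y[te_idx], model.predict(Xte), score, labels=labels)
                )
        mean, sd = _summarize(per_fold)
        out[name] = CVResult(per_fold, mean, sd, [{}] * n_folds)
    return out


def baseline_requires_slogp(features: FeatureMatrix) -> None:
    if not any(n in ("MolLogP", "SLogP") for n in features.names):
        raise UsageError("the SLogP baseline needs a descriptor representation containing SLogP")


# ---------------------------------------------------------------------------
# Final-model training and persistence


@dataclass
class FittedModel:
    """A fully fitted estimator plus everything needed to predict from SMILES."""

    estimator: object
    algorithm: Algorithm
    task: Task
    kind: RepresentationKind
    retained_idx: np.ndarray
    feature_names: list[str]
    params: dict
    seed: int
    version: str = __version_stamp__

    def _featurize(self, smiles_list: Sequence[str]) -> np.ndarray:
        fm = compute_representation(smiles_list, self.kind)
        X = fm.values[:, self.retained_idx]
        if np.isnan(X).any():
            # descriptor failures on novel structures: impute 0 after selection
            X = np.nan_to_num(X, nan=0.0)
        return X

    def predict_smiles(self, smiles_list: Sequence[str]) -> np.ndarray:
        if len(smiles_list) == 0:
            return np.array([])
        return self.estimator.predict(self._featurize(smiles_list))

    def predict_scores_smiles(self, smiles_list: Sequence[str]) -> np.ndarray:
        if len(smiles_list) == 0:
            return np.array([])
        return prediction_scores(self.estimator, self._featurize(smiles_list), self.task)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, directory / "estimator.joblib")
        meta = {
            "algorithm": self.algorithm.value,
            "task": self.task.value,
            "kind": self.kind.value,
            "retained_idx": np.asarray(self.retained_idx).tolist(),
            "feature_names": self.feature_names,
            "params": {k: (v if not isinstance(v, (np.integer, np.floating)) else v.item()) for k, v in self.params.items()},
            "seed": self.seed,
            "version": self.version,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory, expected_kind: Optional[RepresentationKind] = None) -> "FittedModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        if meta["version"] != __version_stamp__:
            raise CompatibilityError(
                f"model version {meta['version']!r} does not match {__version_stamp__!r}"
            )
        kind = RepresentationKind(meta["kind"])
        if expected_kind is not None and RepresentationKind(expected_kind) != kind:
            raise CompatibilityError(
                f"model was fitted on {kind.value}, caller expects {RepresentationKind(expected_kind).value}"
            )
        return cls(
            estimator=joblib.load(directory / "estimator.joblib"),
            algorithm=Algorithm(meta["algorithm"]),
            task=Task(meta["task"]),
            kind=kind,
            retained_idx=np.asarray(meta["retained_idx"], dtype=int),
            feature_names=meta["feature_names"],
            params=meta["params"],
            seed=meta["seed"],
            version=meta["version"],
        )


def train_final_model(
    dataset: LabeledDataset,
    kind: RepresentationKind,
    config: ModelConfig,
    undersample: Optional[bool] = None,
    select: object = "auto",
    features: Optional[FeatureMatrix] = None,
) -> FittedModel:
    """Fit the frozen configuration on the full dataset and package it for
    prediction from SMILES (selection indices, representation kind, seed,
    and a version stamp travel with the estimator)."""
    if not config.fixed_params:
        raise UsageError("train_final_model requires complete fixed_params")
    fm = features if features is not None else compute_representation(dataset.smiles, kind)
    if fm.values.shape[0] != len(dataset):
        raise UsageError("feature rows must align with the dataset")
    do_sel = _should_select(fm, select)
    if do_sel:
        retained, _ = select_features(fm)
    else:
        retained = np.arange(fm.n_features)
    X, y = fm.values[:, retained], dataset.y
    rng = np.random.default_rng(config.seed)
    if _should_undersample(dataset, undersample):
        idx = undersample_indices(y, rng)
        X, y = X[idx], y[idx]
    est = build_estimator(config.algorithm, dataset.task, config.fixed_params, config.seed)
    _fit(est, X, y, config.algorithm, dataset.task)
    return FittedModel(
        estimator=est,
        algorithm=config.algorithm,
        task=dataset.task,
        kind=RepresentationKind(kind),
        retained_idx=np.asarray(retained, dtype=int),
        feature_names=[fm.names[i] for i in retained],
        params=dict(config.fixed_params),
        seed=config.seed,
    )
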