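"""External-set extraction and construction of the six task datasets.

The external validation set is a class-stratified random draw of 10% of the
double-point compounds (per selectivity class, rounded to the nearest
integer); single points never enter it. The six training datasets are:

1/2. all compounds with data for S1R / S2R (binary activity or regression);
3/4. double points excluding nonbinders, labeled selective vs nonselective
     for S1R / S2R (same compounds, different labels);
5/6. double points plus target-inactive single points, 3-class
     (inactive / selective / nonselective) for S1R / S2R.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from rdkit import DataStructs

from .curation import CompoundProfile, PointKind
from .errors import MembershipError, UsageError
from .labeling import SelectivityClass, dataset_label, profile_selectivity


class Task(str, Enum):
    BINARY_ACTIVITY = "binary_activity"
    BINARY_SELECTIVITY = "binary_selectivity"
    MULTICLASS = "multiclass"
    REGRESSION = "regression"


_DATASET_TASK = {
    1: Task.BINARY_ACTIVITY,
    2: Task.BINARY_ACTIVITY,
    3: Task.BINARY_SELECTIVITY,
    4: Task.BINARY_SELECTIVITY,
    5: Task.MULTICLASS,
    6: Task.MULTICLASS,
}


@dataclass
class LabeledDataset:
    dataset_id: int
    smiles: list[str]
    y: np.ndarray
    task: Task

    def __post_init__(self) -> None:
        if len(self.smiles) != len(self.y):
            raise UsageError("smiles and labels must align")
        if len(set(self.smiles)) != len(self.smiles):
            raise UsageError("duplicate canonical SMILES within a dataset")

    def __len__(self) -> int:
        return len(self.smiles)


@dataclass
class SplitResult:
    external: list[CompoundProfile]
    training: list[CompoundProfile]
    seed: int
    per_class_external: dict = field(default_factory=dict)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def extract_external_set(
    profiles: Sequence[CompoundProfile], fraction: float = 0.10, seed: int = 0
) -> SplitResult:
    """Class-stratified external draw over double points.

    For each of the four selectivity classes, round(n_class * fraction)
    compounds are drawn uniformly without replacement; deterministic for a
    fixed seed. Single points always stay in training.
    """
    if not (0 <= fraction < 1):
        raise UsageError(f"fraction must be in [0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    by_class: dict[SelectivityClass, list[CompoundProfile]] = {}
    singles: list[CompoundProfile] = []
    for prof in profiles:
        cls = profile_selectivity(prof)
        if cls == SelectivityClass.UNDEFINED:
            singles.append(prof)
        else:
            by_class.setdefault(cls, []).append(prof)

    external: list[CompoundProfile] = []
    training: list[CompoundProfile] = list(singles)
    per_class: dict[str, int] = {}
    for cls in sorted(by_class, key=lambda c: c.value):
        members = sorted(by_class[cls], key=lambda p: p.canonical_smiles)
        n_take = _round_half_away(len(members) * fraction)
        idx = rng.choice(len(members), size=n_take, replace=False) if n_take else []
        chosen = set(int(i) for i in np.atleast_1d(idx))
        per_class[cls.value] = n_take
        for i, prof in enumerate(members):
            (external if i in chosen else training).append(prof)
    return SplitResult(external=external, training=training, seed=seed, per_class_external=per_class)


def build_dataset(
    dataset_id: int, training: Sequence[CompoundProfile], regression: bool = False
) -> LabeledDataset:
    """Assemble one of the six task datasets from training profiles."""
    if dataset_id not in _DATASET_TASK:
        raise UsageError(f"unknown dataset id {dataset_id}")
    if regression and dataset_id not in (1, 2):
        raise UsageError("regression targets exist only for datasets 1 and 2")
    smiles: list[str] = []
    labels: list[float] = []
    for prof in training:
        try:
            label = dataset_label(prof, dataset_id, regression=regression)
        except MembershipError:
            continue
        smiles.append(prof.canonical_smiles)
        labels.append(label)
    task = Task.REGRESSION if regression else _DATASET_TASK[dataset_id]
    dtype = float if regression else int
    return LabeledDataset(dataset_id, smiles, np.asarray(labels, dtype=dtype), task)


def build_all_datasets(
    training: Sequence[CompoundProfile], include_regression: bool = True
) -> dict[str, LabeledDataset]:
    out = {f"D{i}": build_dataset(i, training) for i in range(1, 7)}
    if include_regression:
        out["D1_reg"] = build_dataset(1, training, regression=True)
        out["D2_reg"] = build_dataset(2, training, regression=True)
    return out


# ---------------------------------------------------------------------------
# Chemical-similarity summaries (ECFP4 Tanimoto)


@dataclass
class TanimotoSummary:
    per_query_max: np.ndarray
    mean_max: float
    median_max: float
    fraction_above: float
    threshold: float


def tanimoto_stats(
    query_fps: Sequence, reference_fps: Sequence, threshold: float = 0.85
) -> TanimotoSummary:
    """Per-query maximum Tanimoto similarity against a reference set.

    Fingerprints are RDKit explicit bit vectors; Tc of two all-zero vectors
    is 0 by convention.
    """
    if len(reference_fps) == 0:
        raise UsageError("reference fingerprint set is empty")
    reference_fps = list(reference_fps)
    ref_empty = np.array([fp.GetNumOnBits() == 0 for fp in reference_fps])
    maxima = []
    for q in query_fps:
        sims = np.asarray(DataStructs.BulkTanimotoSimilarity(q, reference_fps))
        if q.GetNumOnBits() == 0:
            sims[ref_empty] = 0.0  # Tc of two empty sets is 0 by convention
        maxima.append(sims.max())
    maxima = np.asarray(maxima)
    return TanimotoSummary(
        per_query_max=maxima,
        mean_max=float(np.mean(maxima)) if len(maxima) else float("nan"),
        median_max=float(np.median(maxima)) if len(maxima) else float("nan"),
        fraction_above=float(np.mean(maxima > threshold)) if len(maxima) else float("nan"),
        threshold=threshold,
    )


def mean_pairwise_tanimoto(fps: Sequence) -> float:
    """Mean Tanimoto over all unordered pairs in a set (self-pairs excluded)."""
    n = len(fps)
    if n < 2:
        raise UsageError("need at least two fingerprints for pairwise similarity")
    total = 0.0
    count = 0
    fps = list(fps)
    empty = [fp.GetNumOnBits() == 0 for fp in fps]
    for i in range(1, n):
        sims = np.asarray(DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i]))
        if empty[i]:
            sims[np.asarray(empty[:i])] = 0.0
        total += float(sims.sum())
        count += i
    return total / count


def dataset_to_frame(ds: LabeledDataset, label_col: Optional[str] = None):
    import pandas as pd

    col = label_col or ("pactivity" if ds.task == Task.REGRESSION else "label")
    return pd.DataFrame({"canonical_smiles": ds.smiles, col: ds.y})
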