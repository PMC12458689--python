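"""Activity, selectivity, and per-dataset class labels from pActivity profiles.

Thresholds (pActivity scale, -log10 molar):

* active        : pActivity > 5 (i.e. < 10,000 nM); 5.0 exactly is inactive.
* X-selective   : active on X and (at least 100-fold preference,
                  delta-pActivity >= 2, or inactive on the counterpart).
* nonselective  : active on both with |delta| < 2.
* nonbinder     : inactive on both targets.

Single-point compounds (one measured target) get an activity label only.
"""
from __future__ import annotations

import math
from enum import Enum, IntEnum
from typing import Union

from .curation import CompoundProfile, PointKind
from .errors import DomainError, MembershipError, UndefinedError

ACTIVITY_THRESHOLD = 5.0
SELECTIVITY_DELTA = 2.0


class ActivityLabel(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class SelectivityClass(str, Enum):
    S1R_SELECTIVE = "S1R-selective"
    S2R_SELECTIVE = "S2R-selective"
    NONSELECTIVE = "nonselective"
    NONBINDER = "nonbinder"
    UNDEFINED = "undefined"


class MulticlassLabel(IntEnum):
    INACTIVE = 0
    SELECTIVE = 1
    NONSELECTIVE = 2


def activity_label(pactivity: float) -> ActivityLabel:
    """ACTIVE iff pActivity > 5; the boundary 5.0 is INACTIVE."""
    if pactivity is None or not math.isfinite(pactivity):
        raise DomainError(f"pactivity must be finite, got {pactivity}")
    return ActivityLabel.ACTIVE if pactivity > ACTIVITY_THRESHOLD else ActivityLabel.INACTIVE


def selectivity_class(p_s1r: float, p_s2r: float) -> SelectivityClass:
    """Four-way selectivity call for a double-point compound.

    Exactly one class is returned; class(a, b) = S1R-selective iff
    class(b, a) = S2R-selective. Boundary conventions: delta exactly 2 is
    selective; pActivity exactly 5 is inactive.
    """
    for name, v in (("p_s1r", p_s1r), ("p_s2r", p_s2r)):
        if v is None or not math.isfinite(v):
            raise UndefinedError(f"{name} missing or non-finite; route single points elsewhere")
    a1 = p_s1r > ACTIVITY_THRESHOLD
    a2 = p_s2r > ACTIVITY_THRESHOLD
    if a1 and (p_s1r - p_s2r >= SELECTIVITY_DELTA or not a2):
        return SelectivityClass.S1R_SELECTIVE
    if a2 and (p_s2r - p_s1r >= SELECTIVITY_DELTA or not a1):
        return SelectivityClass.S2R_SELECTIVE
    if not a1 and not a2:
        return SelectivityClass.NONBINDER
    return SelectivityClass.NONSELECTIVE


def profile_selectivity(profile: CompoundProfile) -> SelectivityClass:
    """Selectivity of a profile; UNDEFINED for single points."""
    if profile.point_kind == PointKind.SINGLE:
        return SelectivityClass.UNDEFINED
    return selectivity_class(profile.pactivity_s1r, profile.pactivity_s2r)


def dataset_label(
    profile: CompoundProfile, dataset_id: int, regression: bool = False
) -> Union[int, float]:
    """Label of ``profile`` for one of the six task datasets.

    Datasets 1/2: per-target activity (binary 1 = active) or the raw
    pActivity when ``regression``. Datasets 3/4: binary subtype selectivity
    over double points (the opposite-selective class maps to 0, i.e.
    "nonselective" for this target). Datasets 5/6: 3-class per-target label
    (0 inactive / 1 selective / 2 nonselective), where nonbinders and
    target-inactive single points form the inactive class and the
    opposite-selective class collapses into nonselective.
    """
    if dataset_id in (1, 2):
        p = profile.pactivity_s1r if dataset_id == 1 else profile.pactivity_s2r
        if p is None:
            raise MembershipError(f"profile lacks data for dataset {dataset_id}")
        if regression:
            return float(p)
        return int(activity_label(p) == ActivityLabel.ACTIVE)

    if regression:
        raise MembershipError(f"dataset {dataset_id} has no regression target")

    if dataset_id in (3, 4):
        if profile.point_kind != PointKind.DOUBLE:
            raise MembershipError("datasets 3/4 contain double points only")
        cls = selectivity_class(profile.pactivity_s1r, profile.pactivity_s2r)
        if cls == SelectivityClass.NONBINDER:
            raise MembershipError("nonbinders are excluded from datasets 3/4")
        wanted = SelectivityClass.S1R_SELECTIVE if dataset_id == 3 else SelectivityClass.S2R_SELECTIVE
        return int(cls == wanted)

    if dataset_id in (5, 6):
        own_p = profile.pactivity_s1r if dataset_id == 5 else profile.pactivity_s2r
        if profile.point_kind == PointKind.SINGLE:
            if own_p is None or activity_label(own_p) == ActivityLabel.ACTIVE:
                raise MembershipError(
                    f"only single points inactive on the dataset-{dataset_id} target qualify"
                )
            return int(MulticlassLabel.INACTIVE)
        cls = selectivity_class(profile.pactivity_s1r, profile.pactivity_s2r)
        own_sel = SelectivityClass.S1R_SELECTIVE if dataset_id == 5 else SelectivityClass.S2R_SELECTIVE
        if cls == own_sel:
            return int(MulticlassLabel.SELECTIVE)
        if cls == SelectivityClass.NONBINDER:
            return int(MulticlassLabel.INACTIVE)
        return int(MulticlassLabel.NONSELECTIVE)

    raise MembershipError(f"unknown dataset id {dataset_id}")
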