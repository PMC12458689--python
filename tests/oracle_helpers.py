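"""Independent brute-force oracles used by the test suite.

These re-implement the curation aggregation rules, the selectivity
labeling rules, and the classification metrics from first principles,
deliberately sharing no code with the package, so tests can check exact
agreement between the implementation and an independent reading of the
same rules.
"""
from __future__ import annotations

import math

from sigsel.curation import DISCARDED, Measure, Relation


def brute_selectivity(p1: float, p2: float) -> str:
    """Selectivity rules coded directly from their prose definition."""
    active1, active2 = p1 > 5, p2 > 5
    s1 = active1 and (p1 - p2 >= 2 or p2 <= 5)
    s2 = active2 and (p2 - p1 >= 2 or p1 <= 5)
    if s1:
        return "S1R-selective"
    if s2:
        return "S2R-selective"
    if not active1 and not active2:
        return "nonbinder"
    return "nonselective"


_MEASURE_RANK = {Measure.KI: 0, Measure.IC50: 1, Measure.KD: 2, Measure.EC50: 3}


def brute_aggregate(records):
    """Step-by-step duplicate aggregation, coded independently.

    Returns (pactivity, n_merged, is_bound) or the DISCARDED sentinel.
    """
    eq = [r for r in records if r.relation == Relation.EQUAL]
    if eq:
        pool, bound = eq, False
    else:
        best = None
        for r in records:
            if best is None or r.value_nM > best.value_nM:
                best = r
        pool, bound = [best], True
    best_rank = min(_MEASURE_RANK[r.measure] for r in pool)
    pool = [r for r in pool if _MEASURE_RANK[r.measure] == best_rank]
    vals = [r.value_nM for r in pool]
    if len(vals) > 1:
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        if sd >= 0.2 * mean:
            return DISCARDED
        consensus = mean
    else:
        consensus = vals[0]
    return (9.0 - math.log10(consensus), len(vals), bound)


def brute_confusion_metrics(cm):
    """Weighted precision/recall/F1 and multiclass MCC from a confusion
    matrix (rows = truth, columns = prediction), by direct formula."""
    k = len(cm)
    s = sum(sum(row) for row in cm)
    true_counts = [sum(cm[i]) for i in range(k)]
    pred_counts = [sum(cm[i][j] for i in range(k)) for j in range(k)]
    trace = sum(cm[i][i] for i in range(k))

    precisions, recalls, f1s = [], [], []
    for i in range(k):
        tp = cm[i][i]
        prec = tp / pred_counts[i] if pred_counts[i] else 0.0
        rec = tp / true_counts[i] if true_counts[i] else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)

    def weighted(vals):
        return sum(v * t for v, t in zip(vals, true_counts)) / s

    cov = trace * s - sum(p * t for p, t in zip(pred_counts, true_counts))
    den = math.sqrt(s * s - sum(p * p for p in pred_counts)) * math.sqrt(
        s * s - sum(t * t for t in true_counts)
    )
    mcc = cov / den if den else 0.0
    return {
        "PRECISION": weighted(precisions),
        "RECALL": weighted(recalls),
        "F1": weighted(f1s),
        "MCC": mcc,
    }


def confusion_to_labels(cm):
    """Expand a confusion matrix into (y_true, y_pred, one-hot scores)."""
    y_true, y_pred = [], []
    for i, row in enumerate(cm):
        for j, count in enumerate(row):
            y_true.extend([i] * count)
            y_pred.extend([j] * count)
    import numpy as np

    y_true = np.array(y_true)
    y_pred = np.array(y_pred)
    k = len(cm)
    score = np.zeros((len(y_pred), k))
    score[np.arange(len(y_pred)), y_pred] = 1.0
    return y_true, y_pred, score


def enumerate_confusions(k: int, max_total: int):
    """All k x k confusion matrices with every truth class present and
    total count <= max_total."""

    def cells(remaining, n_cells):
        if n_cells == 1:
            for v in range(remaining + 1):
                yield (v,)
            return
        for v in range(remaining + 1):
            for rest in cells(remaining - v, n_cells - 1):
                yield (v,) + rest

    for flat in cells(max_total, k * k):
        cm = [list(flat[i * k : (i + 1) * k]) for i in range(k)]
        if all(sum(row) >= 1 for row in cm):
            yield cm
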