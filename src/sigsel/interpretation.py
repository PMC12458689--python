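"""Feature-importance ranking and 2-D chemical-space embedding.

Importances are the impurity-based weights exposed by fitted tree
ensembles (a permutation-based cross-check is available); the embedding is
t-SNE with the parameters used for train/external overlap visualization
(two components, perplexity 30, learning rate 10).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.inspection import permutation_importance
from sklearn.manifold import TSNE

from .errors import UnsupportedModelError, UsageError


@dataclass
class ImportanceRanking:
    entries: list[tuple[str, float]]  # (feature name, weight), non-increasing
    model_id: str
    top_k: int


def _unwrap(model):
    """Pull the estimator out of a FittedModel or sklearn pipeline."""
    from .modeling import FittedModel

    names = None
    est = model
    if isinstance(model, FittedModel):
        names = list(model.feature_names)
        est = model.estimator
    if hasattr(est, "named_steps"):
        est = est.named_steps.get("model", est)
    return est, names


def top_feature_importances(
    model, names: Optional[Sequence[str]] = None, top_k: int = 15
) -> ImportanceRanking:
    """Top-``top_k`` features by impurity importance, ties broken by
    feature name ascending. Deterministic for a fitted model."""
    est, embedded_names = _unwrap(model)
    if not hasattr(est, "feature_importances_"):
        raise UnsupportedModelError(
            f"{type(est).__name__} exposes no impurity-based feature importances"
        )
    weights = np.asarray(est.feature_importances_, dtype=float)
    names = list(names) if names is not None else embedded_names
    if names is None:
        raise UsageError("feature names are required")
    if len(names) != weights.size:
        raise UsageError(f"got {len(names)} names for {weights.size} features")
    order = sorted(range(weights.size), key=lambda i: (-weights[i], names[i]))
    entries = [(names[i], float(weights[i])) for i in order[:top_k]]
    return ImportanceRanking(entries=entries, model_id=type(est).__name__, top_k=top_k)


def permutation_importances(
    model, X, y, seed: int = 0, n_repeats: int = 5, top_k: int = 15
) -> ImportanceRanking:
    """Permutation-importance cross-check for the impurity ranking."""
    est, embedded_names = _unwrap(model)
    names = embedded_names or [f"f{i}" for i in range(np.asarray(X).shape[1])]
    result = permutation_importance(est, X, y, n_repeats=n_repeats, random_state=seed)
    weights = np.maximum(result.importances_mean, 0.0)
    order = sorted(range(len(names)), key=lambda i: (-weights[i], names[i]))
    entries = [(names[i], float(weights[i])) for i in order[:top_k]]
    return ImportanceRanking(entries=entries, model_id=f"permutation:{type(est).__name__}", top_k=top_k)


def embed_2d(
    fingerprints,
    perplexity: float = 30.0,
    learning_rate: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """t-SNE embedding of fingerprint vectors to n x 2 coordinates.

    Deterministic under a fixed seed (PCA initialization). For
    visualization only.
    """
    X = np.asarray(fingerprints, dtype=float)
    if X.ndim != 2:
        raise UsageError("fingerprints must form a 2-D array")
    if X.shape[0] <= perplexity:
        raise UsageError(f"n = {X.shape[0]} must exceed perplexity = {perplexity}")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(X)
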