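import numpy as np
import pytest

from sigsel.curation import CompoundProfile
from sigsel.datasets import LabeledDataset, Task
from sigsel.featurization import FeatureMatrix, RepresentationKind
from sigsel.synthetic import SyntheticConfig, generate_library


@pytest.fixture(scope="session")
def small_library():
    """A noiseless 200-compound synthetic library with its truth table."""
    cfg = SyntheticConfig(n_compounds=200, noise_sd=0.0, seed=11)
    profiles, truth = generate_library(cfg)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def toy_profiles():
    """Six hand-built profiles covering the dataset membership rules:
    2 nonselective doubles, 1 S1R-selective double, 1 nonbinder double,
    1 active and 1 inactive S1R single point."""
    return [
        CompoundProfile("CCO", 6.5, 6.0),        # nonselective
        CompoundProfile("CCN", 7.0, 6.1),        # nonselective
        CompoundProfile("CCCO", 8.2, 5.9),       # S1R-selective
        CompoundProfile("CCCN", 4.0, 4.5),       # nonbinder
        CompoundProfile("CCCC", 6.7, None),      # single, S1R active
        CompoundProfile("CCCCC", 4.2, None),     # single, S1R inactive
    ]


def make_classification_features(
    n=200, n_features=8, n_classes=2, class_weights=None, sep=3.0, seed=0, dataset_id=3
):
    """Gaussian-cluster features with a separable class signal, wrapped as a
    LabeledDataset + descriptor-kind FeatureMatrix pair."""
    rng = np.random.default_rng(seed)
    if class_weights is None:
        class_weights = [1 / n_classes] * n_classes
    y = rng.choice(n_classes, size=n, p=class_weights)
    centers = rng.normal(0, sep, size=(n_classes, n_features))
    X = centers[y] + rng.normal(0, 1.0, size=(n, n_features))
    smiles = [f"C{'C' * i}" for i in range(n)]  # unique placeholder ids
    task = Task.MULTICLASS if n_classes > 2 else (
        Task.BINARY_SELECTIVITY if dataset_id in (3, 4) else Task.BINARY_ACTIVITY
    )
    ds = LabeledDataset(dataset_id, smiles, y.astype(int), task)
    fm = FeatureMatrix(X, [f"f{i}" for i in range(n_features)], RepresentationKind.DESC_COMPACT_2D)
    return ds, fm


@pytest.fixture()
def separable_binary():
    return make_classification_features(n=240, n_classes=2, seed=5, dataset_id=1)


@pytest.fixture()
def imbalanced_binary():
    return make_classification_features(
        n=200, n_classes=2, class_weights=[0.85, 0.15], seed=7, dataset_id=3
    )
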