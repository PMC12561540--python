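import numpy as np
import pytest

from efsel.data_io import Dataset
from efsel.synthetic_data import SynthSpec, generate


def brute_force_knn(train_X, train_y, query_X, k):
    """Independent KNN oracle: exhaustive distances, explicit tie rules
    (distance ties by row index, vote ties by closest member then label)."""
    preds = []
    for q in query_X:
        d = ((train_X - q) ** 2).sum(axis=1)
        order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
        labels = [train_y[i] for i in order]
        dists = [d[i] for i in order]
        best, best_key = None, None
        for c in set(labels):
            votes = labels.count(c)
            nearest = min(dist for lab, dist in zip(labels, dists) if lab == c)
            key = (-votes, nearest, c)
            if best_key is None or key < best_key:
                best, best_key = c, key
        preds.append(best)
    return np.array(preds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """12 instances, 2 balanced classes, 3 features; feature 0 is class-determining."""
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 6)
    X = np.column_stack(
        [
            y.astype(float),  # perfectly informative
            rng.uniform(size=12),
            rng.uniform(size=12),
        ]
    )
    return Dataset(X=X, y=y, feature_names=["det", "r1", "r2"])


@pytest.fixture
def separable_dataset():
    """Well-separated 2-class Gaussian data, no distractors."""
    ds, truth = generate(
        SynthSpec(
            n_samples=200,
            n_classes=2,
            n_informative=5,
            class_separation=6.0,
            seed=42,
        )
    )
    return ds, truth


@pytest.fixture
def noisy_dataset():
    """Moderate separation plus redundant and noise blocks, with ground truth."""
    ds, truth = generate(
        SynthSpec(
            n_samples=150,
            n_classes=3,
            n_informative=6,
            n_redundant=4,
            n_noise=30,
            class_separation=3.0,
            seed=11,
        )
    )
    return ds, truth
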