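"""Synthetic classification datasets with planted informative structure.

Generates datasets shaped like the wrapper-FS benchmarks (tens to thousands
of features, a handful of classes): a known informative block drawn from
class-conditional Gaussians, a redundant block of noisy linear mixtures of
the informative block, and an irrelevant block of pure noise. The ground
truth mask makes feature-recovery measurable, which no downloaded benchmark
provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset, ValidationError

__all__ = ["SynthSpec", "generate", "recovery_scores"]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset.

    ``class_separation`` is the Euclidean distance between class mean
    vectors in the informative subspace, in units of the within-class
    standard deviation (which is 1).
    """

    n_samples: int
    n_classes: int = 2
    n_informative: int = 10
    n_redundant: int = 0
    n_noise: int = 0
    class_separation: float = 2.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValidationError("need at least one informative feature")
        if self.n_classes < 2:
            raise ValidationError("need at least two classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValidationError("need n_samples >= 2 * n_classes")
        if self.n_redundant < 0 or self.n_noise < 0:
            raise ValidationError("feature counts must be non-negative")
        if self.class_separation < 0:
            raise ValidationError("class_separation must be non-negative")
        if self.redundancy_noise_sd < 0:
            raise ValidationError("redundancy_noise_sd must be non-negative")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def _simplex_vertices(k: int) -> np.ndarray:
    """Vertices of a regular (k-1)-simplex in R^(k-1) with unit pairwise distance."""
    V = np.eye(k) / np.sqrt(2.0)  # pairwise distance 1 in R^k
    V -= V.mean(axis=0)
    # rotate into the (k-1)-dimensional affine hull
    _, _, vt = np.linalg.svd(V, full_matrices=False)
    return V @ vt[: k - 1].T


def _class_means(spec: SynthSpec) -> np.ndarray:
    """Class mean vectors in the informative subspace.

    Regular-simplex placement gives every class pair the same separation;
    when the informative dimension cannot hold a simplex (fewer than
    n_classes-1 informative features) the means fall back to collinear
    placement with adjacent-class separation ``class_separation``.
    """
    k, d = spec.n_classes, spec.n_informative
    means = np.zeros((k, d))
    if d >= k - 1:
        means[:, : k - 1] = _simplex_vertices(k) * spec.class_separation
    else:
        means[:, 0] = np.arange(k) * spec.class_separation
    return means


def generate(spec: SynthSpec) -> tuple[Dataset, np.ndarray]:
    """Draw one dataset; returns (dataset, ground-truth mask).

    The mask is True on informative and redundant columns (both carry class
    signal) and False on noise columns.  Bit-identical for equal seeds.
    """
    rng = np.random.default_rng(spec.seed)
    # as-even-as-possible class sizes
    base = spec.n_samples // spec.n_classes
    sizes = np.full(spec.n_classes, base)
    sizes[: spec.n_samples - base * spec.n_classes] += 1
    y = np.repeat(np.arange(spec.n_classes), sizes)

    means = _class_means(spec)
    X_inf = rng.standard_normal((spec.n_samples, spec.n_informative)) + means[y]

    blocks = [X_inf]
    if spec.n_redundant:
        W = rng.uniform(-1.0, 1.0, size=(spec.n_informative, spec.n_redundant))
        W /= np.linalg.norm(W, axis=0, keepdims=True)
        X_red = X_inf @ W
        if spec.redundancy_noise_sd > 0:
            X_red = X_red + spec.redundancy_noise_sd * rng.standard_normal(X_red.shape)
        blocks.append(X_red)
    if spec.n_noise:
        blocks.append(rng.standard_normal((spec.n_samples, spec.n_noise)))

    X = np.concatenate(blocks, axis=1)
    perm = rng.permutation(spec.n_samples)
    names = (
        [f"inf{j}" for j in range(spec.n_informative)]
        + [f"red{j}" for j in range(spec.n_redundant)]
        + [f"noise{j}" for j in range(spec.n_noise)]
    )
    truth = np.zeros(spec.n_features, dtype=bool)
    truth[: spec.n_informative + spec.n_redundant] = True
    return Dataset(X=X[perm], y=y[perm], feature_names=names), truth


def recovery_scores(
    selected_mask: np.ndarray, truth_mask: np.ndarray
) -> tuple[float, float]:
    """Precision and recall of a selected feature mask against the ground truth."""
    selected_mask = np.asarray(selected_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if selected_mask.shape != truth_mask.shape:
        raise ValidationError("masks must have the same length")
    n_sel = int(selected_mask.sum())
    if n_sel == 0:
        raise ValidationError(
            "empty selection; apply the empty-subset policy before scoring"
        )
    hits = int((selected_mask & truth_mask).sum())
    precision = hits / n_sel
    recall = hits / int(truth_mask.sum())
    return precision, recall
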