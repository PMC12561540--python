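"""Wrapper fitness: KNN cross-validation accuracy plus a subset-size penalty.

The fitness of a feature subset S on a dataset with n features is

    f(S) = beta * (1 - Acc) + (1 - beta) * |S| / n,      minimized,

where Acc is the mean 5-fold stratified CV accuracy of a K=5 nearest-neighbor
classifier restricted to the columns in S, and beta in (0,1) weighs accuracy
against compactness. The held-out test split is touched exactly once per
run, by :func:`validate_on_test`.

KNN is implemented here rather than delegated because wrapper fitness must
be exactly reproducible: neighbor-distance ties break by training-row index,
vote ties by the tied class with the closest member, residual ties by the
smallest encoded label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset, ValidationError, stratified_kfold
from .threshold_control import decode_subset

__all__ = [
    "FitnessSpec",
    "EvaluationResult",
    "knn_predict",
    "cv_accuracy",
    "fitness",
    "evaluate_individual",
    "validate_on_test",
    "WrapperEvaluator",
]

EMPTY_SUBSET_POLICIES = ("worst_fitness", "repair")


@dataclass(frozen=True)
class FitnessSpec:
    """Wrapper-evaluation settings: beta trade-off, K, CV folds, empty-subset policy."""

    beta: float = 0.9
    k_neighbors: int = 5
    cv_folds: int = 5
    empty_subset_policy: str = "worst_fitness"

    def __post_init__(self) -> None:
        if not (0.0 < self.beta < 1.0):
            raise ValidationError("beta must lie strictly between 0 and 1")
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be positive")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.empty_subset_policy not in EMPTY_SUBSET_POLICIES:
            raise ValidationError(
                f"empty_subset_policy must be one of {EMPTY_SUBSET_POLICIES}"
            )


@dataclass(frozen=True)
class EvaluationResult:
    accuracy: float
    subset_size: int
    fitness: float


def _vote(
    labels_sorted: np.ndarray, dist_sorted: np.ndarray, n_classes: int
) -> np.ndarray:
    """Majority vote over neighbor labels listed nearest-first.

    Ties break by the tied class whose nearest member is closest; residual
    ties (equal nearest distances) by the smallest encoded label.
    """
    n_q, k = labels_sorted.shape
    rows = np.arange(n_q)
    flat = rows[:, None] * n_classes + labels_sorted
    counts = np.bincount(flat.ravel(), minlength=n_q * n_classes).reshape(
        n_q, n_classes
    )
    first_dist = np.full((n_q, n_classes), np.inf)
    for j in range(k - 1, -1, -1):
        first_dist[rows, labels_sorted[:, j]] = dist_sorted[:, j]
    tied = counts == counts.max(axis=1, keepdims=True)
    fd = np.where(tied, first_dist, np.inf)
    closest = fd == fd.min(axis=1, keepdims=True)
    return np.argmax(closest, axis=1)  # first True column = smallest label


def knn_predict(
    train_X: np.ndarray, train_y: np.ndarray, query_X: np.ndarray, k: int
) -> np.ndarray:
    """Predict query labels by majority vote among the k Euclidean-nearest rows."""
    train_X = np.asarray(train_X, dtype=np.float64)
    query_X = np.asarray(query_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.int64)
    if train_X.ndim != 2 or query_X.ndim != 2 or train_X.shape[1] != query_X.shape[1]:
        raise ValidationError("train and query matrices must share a feature dimension")
    if train_X.shape[1] < 1:
        raise ValidationError("need at least one feature")
    if k > train_X.shape[0]:
        raise ValidationError(
            f"k={k} exceeds the {train_X.shape[0]} available training rows"
        )
    # squared Euclidean distances via one GEMM; clip tiny negatives
    d2 = (
        np.einsum("ij,ij->i", query_X, query_X)[:, None]
        + np.einsum("ij,ij->i", train_X, train_X)[None, :]
        - 2.0 * (query_X @ train_X.T)
    )
    np.maximum(d2, 0.0, out=d2)
    # stable sort: equal distances keep ascending training-row index
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    n_classes = int(train_y.max()) + 1
    return _vote(train_y[order], np.take_along_axis(d2, order, axis=1), n_classes)


def fitness(acc: float, subset_size: int, n_features: int, beta: float) -> float:
    """Combine accuracy and relative subset size into the minimized objective."""
    if not (0.0 < beta < 1.0):
        raise ValidationError("beta must lie strictly between 0 and 1")
    if not (0.0 <= acc <= 1.0):
        raise ValidationError("accuracy must lie in [0,1]")
    if not (0 <= subset_size <= n_features):
        raise ValidationError("subset_size must lie in [0, n_features]")
    return beta * (1.0 - acc) + (1.0 - beta) * subset_size / n_features


def cv_accuracy(
    ds: Dataset,
    train_indices: np.ndarray,
    mask: np.ndarray,
    spec: FitnessSpec,
    seed: int,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> float:
    """Mean stratified k-fold CV accuracy on the training split, masked columns only.

    ``folds`` may be supplied pre-computed so that every evaluation within a
    run scores candidates on identical partitions (fair-comparison
    contract); otherwise they are derived from ``seed``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask selects no features; apply empty-subset policy")
    if folds is None:
        folds = stratified_kfold(ds, train_indices, spec.cv_folds, seed)
    cols = np.flatnonzero(mask)
    accs = []
    for fit_idx, hold_idx in folds:
        Xf = ds.X[np.ix_(fit_idx, cols)]
        Xh = ds.X[np.ix_(hold_idx, cols)]
        pred = knn_predict(Xf, ds.y[fit_idx], Xh, spec.k_neighbors)
        accs.append(float(np.mean(pred == ds.y[hold_idx])))
    return float(np.mean(accs))


def _apply_empty_policy(
    genotype: np.ndarray, mask: np.ndarray, policy: str
) -> tuple[np.ndarray, bool]:
    """Resolve an empty decoded subset. Returns (mask, is_worst_fitness)."""
    if mask.any():
        return mask, False
    if policy == "worst_fitness":
        return mask, True
    repaired = np.zeros_like(mask)
    repaired[int(np.argmax(genotype))] = True  # keep the strongest gene
    return repaired, False


def evaluate_individual(
    individual,
    theta: float,
    ds: Dataset,
    train_indices: np.ndarray,
    spec: FitnessSpec,
    seed: int,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvaluationResult:
    """Decode, score and cache one individual under the active threshold."""
    mask = decode_subset(individual.genotype, theta)
    mask, worst = _apply_empty_policy(individual.genotype, mask, spec.empty_subset_policy)
    if worst:
        result = EvaluationResult(accuracy=0.0, subset_size=0, fitness=1.0)
    else:
        acc = cv_accuracy(ds, train_indices, mask, spec, seed, folds=folds)
        f = fitness(acc, int(mask.sum()), ds.n_features, spec.beta)
        result = EvaluationResult(accuracy=acc, subset_size=int(mask.sum()), fitness=f)
    individual.fitness = result.fitness
    individual.accuracy = result.accuracy
    individual.subset_size = result.subset_size
    return result


def validate_on_test(
    best,
    theta: float,
    ds: Dataset,
    split,
    spec: FitnessSpec,
) -> tuple[float, int]:
    """Final held-out validation: KNN fit on the whole training split.

    Returns (test accuracy, subset size). The test split plays no role
    before this call.
    """
    mask = decode_subset(best.genotype, theta)
    mask, worst = _apply_empty_policy(best.genotype, mask, spec.empty_subset_policy)
    if worst:
        return 0.0, 0
    cols = np.flatnonzero(mask)
    pred = knn_predict(
        ds.X[np.ix_(split.train_indices, cols)],
        ds.y[split.train_indices],
        ds.X[np.ix_(split.test_indices, cols)],
        spec.k_neighbors,
    )
    return float(np.mean(pred == ds.y[split.test_indices])), int(mask.sum())


class WrapperEvaluator:
    """Reusable evaluator with folds fixed once per run.

    Pre-slices the fold matrices so the per-candidate cost is one column
    gather and one GEMM per fold.
    """

    def __init__(
        self,
        ds: Dataset,
        train_indices: np.ndarray,
        spec: FitnessSpec,
        seed: int,
    ) -> None:
        self.ds = ds
        self.train_indices = np.asarray(train_indices)
        self.spec = spec
        self.seed = seed
        self.folds = stratified_kfold(ds, self.train_indices, spec.cv_folds, seed)
        self._slices = [
            (
                np.ascontiguousarray(ds.X[fit_idx]),
                ds.y[fit_idx],
                np.ascontiguousarray(ds.X[hold_idx]),
                ds.y[hold_idx],
            )
            for fit_idx, hold_idx in self.folds
        ]
        self.n_evaluations = 0

    def accuracy_for_mask(self, mask: np.ndarray) -> float:
        cols = np.flatnonzero(mask)
        accs = []
        for Xf, yf, Xh, yh in self._slices:
            pred = knn_predict(
                Xf[:, cols], yf, Xh[:, cols], self.spec.k_neighbors
            )
            accs.append(float(np.mean(pred == yh)))
        return float(np.mean(accs))

    def __call__(self, individual, theta: float) -> EvaluationResult:
        mask = decode_subset(individual.genotype, theta)
        mask, worst = _apply_empty_policy(
            individual.genotype, mask, self.spec.empty_subset_policy
        )
        if worst:
            result = EvaluationResult(accuracy=0.0, subset_size=0, fitness=1.0)
        else:
            acc = self.accuracy_for_mask(mask)
            f = fitness(acc, int(mask.sum()), self.ds.n_features, self.spec.beta)
            result = EvaluationResult(
                accuracy=acc, subset_size=int(mask.sum()), fitness=f
            )
        individual.fitness = result.fitness
        individual.accuracy = result.accuracy
        individual.subset_size = result.subset_size
        self.n_evaluations += 1
        return result
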