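"""Orchestration of the full feature-selection protocol.

One run = draw a stratified 70/30 split, min-max normalize on the training
rows, fix the stratified CV folds, evolve a population under a 3000-
evaluation budget with the chosen optimizer and threshold controller, then
score the best subset once on the held-out test rows. An experiment repeats
this for ``n_runs`` independent seeds (default 30), each fully replayable
from ``base_seed + run_index``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import Dataset, apply_minmax, fit_minmax, stratified_split
from .optimizers import OptimizerConfig, RunRecord, evolve
from .threshold_control import ThresholdBounds, make_controller
from .wrapper_eval import FitnessSpec, WrapperEvaluator, validate_on_test

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "gtc",
    "aggregate",
    "records_to_jsonl",
    "read_jsonl",
]


@dataclass
class ExperimentConfig:
    """Everything one experiment cell needs: data, optimizer, controller, fitness."""

    dataset: Dataset
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    controller_kind: str = "STATIC"
    controller_params: dict = field(default_factory=dict)
    bounds: ThresholdBounds = field(default_factory=ThresholdBounds)
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    n_runs: int = 30
    base_seed: int = 0
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def horizon(self) -> int:
        """Schedule horizon T = floor(budget / Np), init counted against the budget."""
        return self.optimizer.max_evaluations // self.optimizer.population_size


def gtc(record: RunRecord) -> int:
    """Generation-to-convergence: first generation attaining the final best fitness."""
    trace = record.best_fitness
    final = trace[-1]
    for t, v in enumerate(trace):
        if v == final:
            return t
    return len(trace) - 1  # unreachable; trace contains its own last value


def _single_run(cfg: ExperimentConfig, seed: int) -> RunRecord:
    split = stratified_split(cfg.dataset, cfg.train_fraction, seed)
    params = fit_minmax(cfg.dataset, split.train_indices)
    ds = apply_minmax(params, cfg.dataset)
    evaluator = WrapperEvaluator(ds, split.train_indices, cfg.fitness, seed)
    controller = make_controller(
        cfg.controller_kind,
        bounds=cfg.bounds,
        horizon=cfg.horizon(),
        **cfg.controller_params,
    )
    record = evolve(
        cfg.optimizer, controller, evaluator, ds.n_features, seed, cfg.bounds
    )
    acc, size = validate_on_test(
        record.best_individual, record.best_theta, ds, split, cfg.fitness
    )
    record.test_accuracy = acc
    record.test_subset_size = size
    record.gtc = gtc(record)
    return record


def run_experiment(cfg: ExperimentConfig) -> list[RunRecord]:
    """Execute ``n_runs`` independent runs; run r uses seed base_seed + r.

    A failing run is recorded as a RunRecord with no best individual and the
    error message attached; the remaining runs continue.
    """
    records = []
    for r in range(cfg.n_runs):
        seed = cfg.base_seed + r
        try:
            records.append(_single_run(cfg, seed))
        except Exception as exc:  # noqa: BLE001 - protocol: log and continue
            failed = RunRecord(seed=seed)
            failed.error = f"run {r} (seed {seed}): {exc}"  # type: ignore[attr-defined]
            records.append(failed)
    return records


def aggregate(records: list[RunRecord], fields: list[str] | None = None) -> pd.DataFrame:
    """Mean, sample std (ddof=1) and median of per-run summary fields."""
    fields = fields or ["test_accuracy", "test_subset_size", "gtc"]
    rows = {}
    for name in fields:
        if name == "final_fitness":
            values = [r.best_fitness[-1] for r in records if r.best_fitness]
        else:
            values = [getattr(r, name) for r in records if getattr(r, name) is not None]
        arr = np.asarray(values, dtype=np.float64)
        rows[name] = {
            "mean": float(arr.mean()),
            "std": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "median": float(np.median(arr)),
            "n": int(arr.size),
        }
    return pd.DataFrame(rows).T


def records_to_jsonl(records: list[RunRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_jsonl(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]
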