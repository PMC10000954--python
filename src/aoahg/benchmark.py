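"""Benchmark harness: optimizers x classifiers x seeds on one dataset.

Each cell runs a wrapper-FS driver on the training partition, then scores
the final selected subset on the held-out test partition with the same
classifier back-end, reporting accuracy (AC), balanced accuracy (BA),
F1 (F), recall (R), precision (P) and the driver wall-clock time (ET),
plus the selected-feature count and the best fitness.  Rows are exactly
reproducible from (optimizer, classifier, seed, mask).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .classifiers import CLASSIFIER_LABELS, MetricsReport, compute_metrics, train_and_predict
from .data import EmbeddingDataset, generate_embedding_dataset, load_dataset
from .optimizers import OptimizerParams
from .selection import FeatureMask, run_optimizer

OPTIMIZER_LABELS = ("aoahg", "aoa", "hgs")

RESULT_COLUMNS = [
    "optimizer",
    "classifier",
    "seed",
    "AC",
    "BA",
    "F",
    "R",
    "P",
    "ET",
    "selected",
    "fitness",
    "mask",
]

__all__ = [
    "OPTIMIZER_LABELS",
    "BenchmarkConfig",
    "evaluate_mask_on_test",
    "run_benchmark",
]


@dataclass
class BenchmarkConfig:
    """Declarative description of one benchmark sweep."""

    optimizers: Sequence[str] = OPTIMIZER_LABELS
    classifiers: Sequence[str] = CLASSIFIER_LABELS
    pop_size: int = 50
    max_iter: int = 20
    seeds: Sequence[int] = (0,)
    lam: float = 0.99
    dataset_path: Optional[str] = None
    generator: Optional[dict] = None
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.optimizers) - set(OPTIMIZER_LABELS)
        if unknown:
            raise ValueError(f"unknown optimizers: {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIER_LABELS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        if not self.seeds:
            raise ValueError("need at least one seed")

    @property
    def repeats(self) -> int:
        return len(self.seeds)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def resolve_dataset(self) -> EmbeddingDataset:
        if self.dataset_path:
            return load_dataset(self.dataset_path)
        if self.generator:
            return generate_embedding_dataset(**self.generator)
        raise ValueError("config must give dataset_path or generator parameters")


def evaluate_mask_on_test(
    data: EmbeddingDataset,
    mask: FeatureMask,
    classifier_spec: str,
    seed: int,
) -> MetricsReport:
    """Train on the full training partition restricted to the mask and
    score the held-out test partition.  Deterministic given (mask, seed)."""
    if mask.count == 0:
        raise ValueError("cannot evaluate an empty feature subset")
    cols = mask.indices()
    X_tr, y_tr = data.train_arrays()
    X_te, y_te = data.test_arrays()
    Xf = X_tr[:, cols]
    mu = Xf.mean(axis=0)
    sd = Xf.std(axis=0)
    sd[sd == 0] = 1.0
    pred = train_and_predict(
        classifier_spec, (Xf - mu) / sd, y_tr, (X_te[:, cols] - mu) / sd, seed
    )
    return compute_metrics(y_te, pred)


def run_benchmark(
    config: BenchmarkConfig, data: Optional[EmbeddingDataset] = None
) -> pd.DataFrame:
    """Run the full cross of optimizers x classifiers x seeds.

    Returns one row per cell plus, per (optimizer, classifier), an
    aggregate row with seed = "mean".  The mask column stores the selected
    subset as a 0/1 string so every row can be replayed exactly.
    """
    if data is None:
        data = config.resolve_dataset()
    rows = []
    for opt in config.optimizers:
        for clf in config.classifiers:
            for seed in config.seeds:
                params = OptimizerParams(
                    pop_size=config.pop_size,
                    max_iter=config.max_iter,
                    lam=config.lam,
                    seed=int(seed),
                )
                res = run_optimizer(opt, data, params, clf)
                rep = evaluate_mask_on_test(data, res.best_mask, clf, int(seed))
                rows.append(
                    {
                        "optimizer": opt,
                        "classifier": clf,
                        "seed": int(seed),
                        "AC": rep.accuracy,
                        "BA": rep.balanced_accuracy,
                        "F": rep.f1,
                        "R": rep.recall,
                        "P": rep.precision,
                        "ET": res.elapsed,
                        "selected": res.selected_count,
                        "fitness": res.best_fitness,
                        "mask": "".join(map(str, res.best_mask.bits)),
                    }
                )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    means = (
        table.groupby(["optimizer", "classifier"], sort=False)[
            ["AC", "BA", "F", "R", "P", "ET", "selected", "fitness"]
        ]
        .mean()
        .reset_index()
    )
    means["seed"] = "mean"
    means["mask"] = ""
    out = pd.concat([table, means[RESULT_COLUMNS]], ignore_index=True)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "benchmark_results.csv", index=False)
        config.to_yaml(outdir / "config_snapshot.yaml")
    return out
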