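"""Synthetic deep-embedding datasets and feature-matrix I/O.

The generator emulates the setting the toolkit targets: fixed-length image
embeddings (default 128 columns, the width of a pointwise-convolution
feature head) in which only a planted subset of columns carries class
signal.  Class-conditional means of the informative columns sit at the
vertices of a regular simplex tiled across those columns, so every
informative column carries an equal share of the between-class separation;
the remaining columns are pure standard-Gaussian noise.  The ground-truth
informative mask is recorded so selection quality can be scored.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

__all__ = [
    "EmbeddingDataset",
    "generate_embedding_dataset",
    "informative_recovery",
    "load_dataset",
]


@dataclass
class EmbeddingDataset:
    """A feature matrix with labels, a frozen train/test split and, for
    synthetic data, the planted informative-feature mask."""

    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    informative_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)
    feature_names: Optional[list] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError("X and y length mismatch")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        overlap = np.intersect1d(self.train_idx, self.test_idx)
        if overlap.size:
            raise ValueError("train/test indices overlap")
        if self.feature_names is None:
            self.feature_names = [f"f{j:03d}" for j in range(self.X.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)

    def train_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.X[self.train_idx], self.y[self.train_idx]

    def test_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.X[self.test_idx], self.y[self.test_idx]

    # ---------------------------------------------------------------- I/O
    def save_npz(self, path: Union[str, Path]) -> None:
        """Write arrays named X, y plus split indices and metadata."""
        extras = {}
        if self.informative_mask is not None:
            extras["informative_mask"] = np.asarray(self.informative_mask, dtype=np.int8)
        np.savez(
            path,
            X=self.X,
            y=self.y,
            train_idx=self.train_idx,
            test_idx=self.test_idx,
            meta=np.array(json.dumps(self.meta)),
            feature_names=np.array(self.feature_names),
            **extras,
        )

    @classmethod
    def load_npz(cls, path: Union[str, Path]) -> "EmbeddingDataset":
        with np.load(path, allow_pickle=False) as z:
            mask = z["informative_mask"].astype(np.int8) if "informative_mask" in z else None
            meta = json.loads(str(z["meta"])) if "meta" in z else {}
            names = [str(n) for n in z["feature_names"]] if "feature_names" in z else None
            if "train_idx" in z:
                train_idx, test_idx = z["train_idx"], z["test_idx"]
            else:
                train_idx, test_idx = _stratified_split(z["y"], 0.8, 0)
            return cls(z["X"], z["y"], train_idx, test_idx, mask, meta, names)

    def save_csv(self, path: Union[str, Path], label_column: str = "label") -> None:
        """Write a header CSV: one numeric column per feature plus the label.

        The split and the informative mask are not representable in the CSV
        dialect; loading re-derives a stratified split.
        """
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def load_csv(
        cls,
        path: Union[str, Path],
        label_column: str = "label",
        train_frac: float = 0.8,
        seed: int = 0,
    ) -> "EmbeddingDataset":
        df = pd.read_csv(path)
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        y = df[label_column].to_numpy(dtype=int)
        feats = df.drop(columns=[label_column])
        train_idx, test_idx = _stratified_split(y, train_frac, seed)
        return cls(
            feats.to_numpy(dtype=float),
            y,
            train_idx,
            test_idx,
            meta={"source": str(path), "train_frac": train_frac, "split_seed": seed},
            feature_names=list(feats.columns),
        )


def load_dataset(path: Union[str, Path], **kwargs) -> EmbeddingDataset:
    """Dispatch on extension: .npz or delimited text with a label column."""
    path = Path(path)
    if path.suffix == ".npz":
        return EmbeddingDataset.load_npz(path)
    return EmbeddingDataset.load_csv(path, **kwargs)


def _stratified_split(
    y: np.ndarray, train_frac: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def _class_means(
    n_classes: int, k: int, class_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Class centroids for the informative columns.

    Regular-simplex vertices (C points, all pairwise distances equal) are
    tiled across the k columns and given random per-column sign flips, then
    rescaled so the mean pairwise centroid distance equals ``class_sep``.
    Tiling spreads the separation evenly over the columns, so no single
    column dominates and removing any informative column costs signal.
    """
    c = n_classes
    # simplex in R^(c-1): rows of the centred identity, orthonormalised span
    eye = np.eye(c)
    centred = eye - eye.mean(axis=0)
    # project onto a (c-1)-dim basis of the centred hyperplane
    q, _ = np.linalg.qr(centred.T)
    verts = centred @ q[:, : c - 1]  # c x (c-1), pairwise distance sqrt(2)
    cols = np.tile(verts, (1, int(np.ceil(k / (c - 1)))))[:, :k]
    signs = rng.choice([-1.0, 1.0], size=k)
    cols = cols * signs
    d = np.sqrt(((cols[:, None, :] - cols[None, :, :]) ** 2).sum(-1))
    mean_pair = d[np.triu_indices(c, 1)].mean()
    return cols * (class_sep / mean_pair)


def generate_embedding_dataset(
    n: int,
    dim: int = 128,
    k_informative: int = 10,
    n_classes: int = 2,
    class_sep: float = 3.0,
    noise_sd: float = 1.0,
    train_frac: float = 0.8,
    seed: int = 0,
) -> EmbeddingDataset:
    """Generate an embedding-like dataset with a planted informative subset.

    Informative columns get class-dependent Gaussian means (centroids
    separated by ``class_sep``, jittered with ``noise_sd``); the other
    columns are standard Gaussian noise.  A stratified train/test split at
    ``train_frac`` and the ground-truth mask are recorded.
    """
    if not 1 <= k_informative <= dim:
        raise ValueError("need 1 <= k_informative <= dim")
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n < 4 * n_classes:
        raise ValueError("need n >= 4 * n_classes")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    # near-balanced classes, randomly ordered
    y = rng.permutation(np.arange(n) % n_classes)

    means = _class_means(n_classes, k_informative, class_sep, rng)
    X = rng.standard_normal((n, dim))
    informative_cols = np.sort(rng.permutation(dim)[:k_informative])
    X[:, informative_cols] = means[y] + noise_sd * rng.standard_normal((n, k_informative))

    mask = np.zeros(dim, dtype=np.int8)
    mask[informative_cols] = 1
    train_idx, test_idx = _stratified_split(y, train_frac, seed)
    meta = {
        "n": n,
        "dim": dim,
        "k_informative": k_informative,
        "n_classes": n_classes,
        "class_sep": class_sep,
        "noise_sd": noise_sd,
        "train_frac": train_frac,
        "seed": seed,
    }
    return EmbeddingDataset(X, y, train_idx, test_idx, mask, meta)


def informative_recovery(selected, truth) -> Tuple[float, float]:
    """Recall and precision of a selected mask against the planted truth."""
    sel = np.asarray(getattr(selected, "bits", selected), dtype=int)
    tru = np.asarray(getattr(truth, "bits", truth), dtype=int)
    if sel.shape != tru.shape:
        raise ValueError("mask length mismatch")
    inter = int(np.sum((sel == 1) & (tru == 1)))
    n_true = int(tru.sum())
    n_sel = int(sel.sum())
    recall = inter / n_true if n_true else 0.0
    precision = inter / n_sel if n_sel else 0.0
    return recall, precision
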