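"""Core data containers and plain-text interchange formats.

Feature tables travel as CSV (header row, first column sample id, remaining
columns numeric features) with a companion label column file whose values
lie in {+1, -1, 0}; 0 marks an unlabeled sample.  Affinity graphs serialize
to a 3-column edge list (i, j, weight) with 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "FeatureMatrix",
    "PartialLabels",
    "AffinityGraph",
    "Laplacian",
    "read_features_csv",
    "write_features_csv",
    "read_labels_csv",
    "write_labels_csv",
    "save_edge_list",
    "load_edge_list",
]


@dataclass
class FeatureMatrix:
    """An n x d matrix of sample features (rows = samples)."""

    values: np.ndarray
    sample_ids: Sequence[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"feature matrix must be 2-D, got shape {self.values.shape}")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise DataError(f"need n >= 1 samples and d >= 1 features, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature matrix contains non-finite entries")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class PartialLabels:
    """Length-n labels over {+1, -1, 0}; 0 marks an unlabeled sample."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise DataError("labels must be a 1-D sequence")
        if not np.all(np.isin(self.labels, (-1, 0, 1))):
            raise DataError("labels must take values in {+1, -1, 0}")
        if self.l < 1:
            raise DataError("need at least one labeled sample")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.labels != 0

    @property
    def l(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def u(self) -> int:
        return self.n - self.l


@dataclass
class AffinityGraph:
    """Symmetric nonnegative KNN/RBF affinity matrix with zero diagonal."""

    weights: np.ndarray
    k: int
    sigma: float

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise DataError("affinity matrix must be square")
        if not np.array_equal(W, W.T):
            raise DataError("affinity matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise DataError("affinity matrix must have a zero diagonal")
        if W.min() < 0 or W.max() > 1:
            raise DataError("affinity weights must lie in [0, 1]")
        self.weights = W


@dataclass
class Laplacian:
    """Graph Laplacian L = D - (s + s^T)/2 of a similarity matrix."""

    L: np.ndarray
    D: np.ndarray


def read_features_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError("feature CSV needs an id column plus >= 1 feature column")
    ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return FeatureMatrix(values, ids)


def write_features_csv(path, X: FeatureMatrix) -> None:
    cols = [f"f{j}" for j in range(X.d)]
    df = pd.DataFrame(X.values, columns=cols)
    df.insert(0, "sample_id", list(X.sample_ids))
    df.to_csv(path, index=False)


def read_labels_csv(path) -> PartialLabels:
    df = pd.read_csv(path)
    col = df.columns[-1]
    return PartialLabels(df[col].to_numpy(dtype=int))


def write_labels_csv(path, y: PartialLabels, sample_ids=None) -> None:
    ids = list(sample_ids) if sample_ids is not None else list(range(y.n))
    pd.DataFrame({"sample_id": ids, "label": y.labels}).to_csv(path, index=False)


def save_edge_list(path, weights: np.ndarray) -> None:
    """Write nonzero upper-triangle entries as ``i,j,weight`` rows (0-based)."""
    W = np.asarray(weights, dtype=float)
    iu, ju = np.nonzero(np.triu(W, k=1))
    with open(path, "w") as fh:
        fh.write("i,j,weight\n")
        for i, j in zip(iu, ju):
            fh.write(f"{i},{j},{float(W[i, j])!r}\n")


def load_edge_list(path, n: int) -> np.ndarray:
    df = pd.read_csv(path)
    W = np.zeros((n, n))
    for i, j, w in df.itertuples(index=False):
        W[int(i), int(j)] = w
        W[int(j), int(i)] = w
    return W
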