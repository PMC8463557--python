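"""Dissimilarity matrices over feature-matrix rows."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix

__all__ = ["DistanceMatrix", "euclidean_distances", "bray_curtis"]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray
    labels: list[str] | None = None
    metric: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.data.shape} does not match {n} ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.data < -1e-12):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.data, 0.0)
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("labels length must match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


def euclidean_distances(m: FeatureMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between feature-matrix rows."""
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    d = squareform(pdist(m.values, metric="euclidean"))
    return DistanceMatrix(list(m.ids), d, list(m.labels), metric="euclidean")


def bray_curtis(m: FeatureMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities: sum|x-y| / sum(x+y)."""
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.any(m.values < 0):
        raise ValueError("Bray-Curtis requires non-negative values")
    zero_rows = np.flatnonzero(m.values.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(
            f"Bray-Curtis undefined for all-zero row '{m.ids[zero_rows[0]]}'"
        )
    d = squareform(pdist(m.values, metric="braycurtis"))
    return DistanceMatrix(list(m.ids), d, list(m.labels), metric="braycurtis")
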