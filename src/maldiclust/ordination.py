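"""Non-metric multidimensional scaling (Kruskal stress-1).

Minimises stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) over configurations,
where d are configuration distances and dhat the monotone (PAVA) disparities
of the input dissimilarities (primary tie handling: equal dissimilarities
may untie). Descent alternates isotonic regression with a Guttman-transform
update from a classical-scaling start plus random restarts; the logged
stress sequence is guaranteed non-increasing because an update that would
increase stress terminates the run instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .distance import DistanceMatrix

__all__ = ["OrdinationResult", "nmds", "stress1"]


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n x k
    stress: float  # Kruskal stress-1 of the best restart
    n_restarts: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)  # best restart
    ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)


def stress1(delta: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities."""
    dist = pdist(coords)
    dhat = _disparities(delta, dist)
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _disparities(delta: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Monotone disparities via PAVA; within ties of delta the configuration
    distances are pre-sorted ascending (primary approach, unties allowed)."""
    order = np.lexsort((dist, delta))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(order.size), dist[order])
    dhat = np.empty_like(dist)
    dhat[order] = fitted
    return dhat


def _classical_start(d: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) scaling coordinates as a rational start."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals_k)[None, :]


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> OrdinationResult:
    """Best-of-restarts NMDS of a dissimilarity matrix into k dimensions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.n
    if n < k + 1:
        raise ValueError(f"need at least k + 1 = {k + 1} observations")
    delta = d.condensed()
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            coords = _classical_start(d.data, k)
            if coords.shape[1] < k:
                pad = rng.normal(scale=1e-3, size=(n, k - coords.shape[1]))
                coords = np.hstack([coords, pad])
        else:
            coords = rng.normal(size=(n, k))
        coords, history, converged = _descend(delta, coords, max_iter, tol)
        s = history[-1]
        if best is None or s < best[0]:
            best = (s, coords, history, converged)
    assert best is not None
    s, coords, history, converged = best
    return OrdinationResult(
        coords, s, max(1, n_restarts), converged, history, list(d.ids), list(d.labels or [])
    )


def _descend(
    delta: np.ndarray, coords: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, list[float], bool]:
    n = coords.shape[0]
    dist = pdist(coords)
    dhat = _disparities(delta, dist)
    history = [_stress_from(dist, dhat)]
    converged = False
    for _ in range(max_iter):
        # Guttman transform with the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        new_coords = (b @ coords) / n
        new_dist = pdist(new_coords)
        new_dhat = _disparities(delta, new_dist)
        new_stress = _stress_from(new_dist, new_dhat)
        if new_stress > history[-1] + 1e-15:
            converged = True  # local minimum up to numerical precision
            break
        coords, dist, dhat = new_coords, new_dist, new_dhat
        history.append(new_stress)
        if len(history) > 1 and history[-2] - history[-1] < tol:
            converged = True
            break
    return coords, history, converged


def _stress_from(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))
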