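"""Ward clustering of spectra and multiscale-bootstrap edge support.

The dendrogram uses the Ward criterion on (Euclidean) distances in its
"2D" form: the Lance-Williams recurrence is applied to squared distances
and heights are reported on the distance scale, so merging two singletons
at distance d yields a merge height of exactly d.

Edge support follows the multiscale bootstrap: features are resampled at a
ladder of sampling ratios r, the tree is rebuilt per replicate, and each
original internal edge's recovery frequency BP_r is probit-transformed and
fitted by weighted least squares to ``z(r) = v * sqrt(r) + c / sqrt(r)``.
The approximately unbiased support is ``AU = 1 - Phi(v - c)`` and BP is the
raw recovery proportion at r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.special import ndtr, ndtri

from .distance import DistanceMatrix
from .features import FeatureMatrix

__all__ = ["Dendrogram", "MultiscaleBootstrapParams", "ward_cluster", "au_bp", "to_newick"]


@dataclass
class Dendrogram:
    """Agglomerative merge tree with optional per-edge AU/BP support.

    ``linkage_matrix`` is in scipy format: row k merges clusters
    ``Z[k, 0]`` and ``Z[k, 1]`` at height ``Z[k, 2]``; support arrays are
    aligned with linkage rows (internal edges).
    """

    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    leaf_labels: list[str] | None = None
    au_pct: np.ndarray | None = None
    bp_pct: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.linkage_matrix = np.asarray(self.linkage_matrix, dtype=float)
        n = len(self.leaf_ids)
        if self.linkage_matrix.shape[0] != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def clades(self) -> list[frozenset[int]]:
        """Leaf-index sets of the internal nodes, one per linkage row."""
        return _clades_from_linkage(self.linkage_matrix, self.n_leaves)

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels from cutting the tree into ``n_clusters``."""
        return fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")


@dataclass(frozen=True)
class MultiscaleBootstrapParams:
    """Multiscale bootstrap settings (scale ladder, replicates, seed)."""

    scales: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
    replicates_per_scale: int = 10_000
    seed: int = 0
    resample: str = "features"  # or "rows"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.scales):
            raise ValueError("all scales must be positive")
        if self.replicates_per_scale < 1:
            raise ValueError("replicates_per_scale must be >= 1")
        if self.resample not in ("features", "rows"):
            raise ValueError("resample must be 'features' or 'rows'")


def ward_cluster(d: DistanceMatrix) -> Dendrogram:
    """Ward-2D agglomeration of a distance matrix.

    Heights are non-decreasing; ties are resolved deterministically by
    scipy's nearest-neighbor-chain order.
    """
    if d.n < 2:
        raise ValueError("need at least 2 observations to cluster")
    z = linkage(d.condensed(), method="ward")
    return Dendrogram(z, list(d.ids), list(d.labels) if d.labels else None)


def _clades_from_linkage(z: np.ndarray, n: int) -> list[frozenset[int]]:
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    clades: list[frozenset[int]] = []
    for a, b in z[:, :2].astype(int):
        merged = members[a] | members[b]
        members.append(merged)
        clades.append(merged)
    return clades


def au_bp(
    m: FeatureMatrix,
    params: MultiscaleBootstrapParams | None = None,
) -> Dendrogram:
    """Ward dendrogram with multiscale-bootstrap AU and BP percentages.

    Features (columns) are resampled with replacement at size
    ``round(p * r)`` for every scale r; per edge, recovery counts are
    clamped to ``[0.5, B - 0.5]`` before the probit so the fit stays
    finite. An edge never recovered at any scale gets AU = 0 with its
    ``degenerate`` flag set.
    """
    params = params or MultiscaleBootstrapParams()
    if params.resample != "features":
        raise NotImplementedError(
            "only feature (column) resampling is meaningful when the "
            "clustered objects are the spectra themselves"
        )
    values = m.values
    n, p = values.shape
    if p < 2:
        raise ValueError("need at least 2 features to bootstrap")
    base = linkage(pdist(values, metric="euclidean"), method="ward")
    clades0 = _clades_from_linkage(base, n)
    n_edges = len(clades0)
    clade_index = {c: k for k, c in enumerate(clades0)}

    scales = np.asarray(params.scales, dtype=float)
    B = params.replicates_per_scale
    rng = np.random.default_rng(params.seed)
    counts = np.zeros((scales.size, n_edges), dtype=np.int64)
    for si, r in enumerate(scales):
        size = max(2, int(round(p * r)))
        for _ in range(B):
            cols = rng.integers(0, p, size=size)
            sub = values[:, cols]
            zb = linkage(pdist(sub, metric="euclidean"), method="ward")
            for clade in _clades_from_linkage(zb, n):
                k = clade_index.get(clade)
                if k is not None:
                    counts[si, k] += 1

    au = np.empty(n_edges)
    bp = np.empty(n_edges)
    degenerate = np.zeros(n_edges, dtype=bool)
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    for k in range(n_edges):
        bp[k] = 100.0 * counts[r1, k] / B
        if counts[:, k].sum() == 0:
            au[k] = 0.0
            degenerate[k] = True
            continue
        if np.all(counts[:, k] == B):
            au[k] = 100.0
            continue
        v, c = fit_msboot(counts[:, k], scales, B)
        au[k] = 100.0 * (1.0 - ndtr(v - c))

    dendro = Dendrogram(
        base,
        list(m.ids),
        list(m.labels),
        au_pct=au,
        bp_pct=bp,
        degenerate=degenerate,
    )
    return dendro


def fit_msboot(counts: np.ndarray, scales: np.ndarray, B: int) -> tuple[float, float]:
    """Fit ``z(r) = v sqrt(r) + c / sqrt(r)`` to per-scale recovery counts.

    The model is a binomial probit regression of the non-recovery
    frequency on (sqrt(r), 1/sqrt(r)), fitted by iteratively re-weighted
    least squares. The starting step is the one-shot weighted fit of
    ``z_r = Phi^-1(1 - BP_r)`` with counts clamped to ``[0.5, B - 0.5]``
    and binomial delta-method weights; further IRLS steps remove the
    clamping bias at scales where recovery saturates at 0 or B.
    """
    counts = np.asarray(counts, dtype=float)
    failures = B - counts  # modelled success = "edge not recovered"
    x = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])

    clamped = np.clip(counts, 0.5, B - 0.5)
    z = ndtri(1.0 - clamped / B)
    phi = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
    bp_r = clamped / B
    w = B * phi**2 / (bp_r * (1.0 - bp_r))
    wx = x * w[:, None]
    beta = np.linalg.solve(x.T @ wx, wx.T @ z)

    for _ in range(25):
        eta = np.clip(x @ beta, -8.0, 8.0)
        mu = np.clip(ndtr(eta), 1e-12, 1.0 - 1e-12)
        phi = np.exp(-0.5 * eta**2) / np.sqrt(2.0 * np.pi)
        w = B * phi**2 / (mu * (1.0 - mu))
        z_work = eta + (failures / B - mu) / phi
        wx = x * w[:, None]
        new_beta = np.linalg.solve(x.T @ wx, wx.T @ z_work)
        if np.max(np.abs(new_beta - beta)) < 1e-10:
            beta = new_beta
            break
        beta = new_beta
    return float(beta[0]), float(beta[1])


def to_newick(d: Dendrogram, decimals: int = 6) -> str:
    """Newick export with internal labels ``AU|BP`` (one decimal place).

    Branch lengths are height differences between a node and its parent
    merge (leaves hang from their first merge).
    """
    z = d.linkage_matrix
    n = d.n_leaves
    heights = np.concatenate([np.zeros(n), z[:, 2]])

    def node_label(k: int) -> str:
        if d.au_pct is None or d.bp_pct is None:
            return ""
        return f"{d.au_pct[k]:.1f}|{d.bp_pct[k]:.1f}"

    def render(idx: int, parent_height: float) -> str:
        length = max(parent_height - heights[idx], 0.0)
        if idx < n:
            name = str(d.leaf_ids[idx]).replace(" ", "_").replace(",", "_")
            return f"{name}:{length:.{decimals}f}"
        k = idx - n
        a, b = int(z[k, 0]), int(z[k, 1])
        inner = f"({render(a, heights[idx])},{render(b, heights[idx])})"
        return f"{inner}{node_label(k)}:{length:.{decimals}f}"

    root = n + (n - 1) - 1
    a, b = int(z[-1, 0]), int(z[-1, 1])
    h = heights[root]
    label = node_label(n - 2)
    return f"({render(a, h)},{render(b, h)}){label};"
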