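"""Permutation and dispersion tests on dissimilarity matrices.

``permanova`` is the one-way pseudo-F permutation test computed directly
from the distance matrix; ``dispersion_homogeneity`` embeds the matrix by
principal coordinates (keeping negative-eigenvalue axes as imaginary
parts), measures each sample's distance to its group centroid, and runs a
one-way ANOVA on those distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f_oneway

from .distance import DistanceMatrix

__all__ = ["PermTestResult", "permanova", "dispersion_homogeneity"]


@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    method: str = ""


def _group_indices(labels: list[str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return {lab: np.asarray(idx) for lab, idx in groups.items()}


def permanova(
    d: DistanceMatrix,
    labels: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> PermTestResult:
    """One-way PERMANOVA (pseudo-F with a permutation p-value).

    SS_total = sum_{i<j} d_ij^2 / n, SS_within = sum_g sum_{i<j in g}
    d_ij^2 / n_g, F = (SS_between / (g - 1)) / (SS_within / (n - g)), and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) over random relabelings.
    """
    labels = list(labels if labels is not None else (d.labels or []))
    n = d.n
    if len(labels) != n:
        raise ValueError("labels length must match the distance matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    groups = _group_indices(labels)
    g = len(groups)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n - g < 1:
        raise ValueError("PERMANOVA needs residual degrees of freedom")

    d2 = d.data**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    sizes = np.array([idx.size for idx in groups.values()])

    def pseudo_f(label_idx: np.ndarray) -> float:
        # label_idx: array of group codes per sample
        ss_within = 0.0
        for code, n_g in enumerate(sizes):
            members = np.flatnonzero(label_idx == code)
            block = d2[np.ix_(members, members)]
            ss_within += block.sum() / (2.0 * n_g)
        ss_between = ss_total - ss_within
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    codes = np.empty(n, dtype=int)
    for code, idx in enumerate(groups.values()):
        codes[idx] = code
    f_obs = pseudo_f(codes)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(codes)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermTestResult(float(f_obs), float(p), n_perm, seed, method="permanova")


def pcoa_embedding(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate axes of a dissimilarity matrix.

    Returns ``(real_axes, imag_axes)``: axes for positive eigenvalues and,
    separately, axes for negative eigenvalues (their imaginary parts).
    """
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d.data**2) @ j
    vals, vecs = np.linalg.eigh(b)
    tol = 1e-8 * max(1.0, float(np.abs(vals).max()))
    pos = vals > tol
    neg = vals < -tol
    real_axes = vecs[:, pos] * np.sqrt(vals[pos])[None, :]
    imag_axes = vecs[:, neg] * np.sqrt(-vals[neg])[None, :]
    return real_axes, imag_axes


def dispersion_homogeneity(
    d: DistanceMatrix,
    labels: list[str] | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> PermTestResult:
    """Homogeneity-of-dispersion test (betadisper-style).

    Distances to group centroids are computed in the principal-coordinate
    space as ``sqrt(max(real_part^2 - imag_part^2, 0))`` and compared by a
    one-way ANOVA F with its parametric p-value; with ``n_perm > 0`` the
    p-value is computed by permuting the dispersion vector instead.
    """
    labels = list(labels if labels is not None else (d.labels or []))
    if len(labels) != d.n:
        raise ValueError("labels length must match the distance matrix")
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("dispersion test needs at least 2 groups")
    for lab, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"group '{lab}' has fewer than 2 members")

    real_axes, imag_axes = pcoa_embedding(d)
    z = np.empty(d.n)
    for idx in groups.values():
        c_real = real_axes[idx].mean(axis=0)
        c_imag = imag_axes[idx].mean(axis=0) if imag_axes.size else np.zeros(0)
        sq_real = ((real_axes[idx] - c_real) ** 2).sum(axis=1)
        sq_imag = ((imag_axes[idx] - c_imag) ** 2).sum(axis=1) if imag_axes.size else 0.0
        z[idx] = np.sqrt(np.maximum(sq_real - sq_imag, 0.0))

    samples = [z[idx] for idx in groups.values()]
    f_stat, p_param = f_oneway(*samples)
    f_stat = float(f_stat)
    if not np.isfinite(f_stat):  # identical dispersions in every group
        f_stat, p_param = 0.0, 1.0
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        codes = np.empty(d.n, dtype=int)
        for code, idx in enumerate(groups.values()):
            codes[idx] = code
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            f_p, _ = f_oneway(*[z[perm == code] for code in range(len(groups))])
            if not np.isfinite(f_p):
                f_p = 0.0
            if f_p >= f_stat:
                count += 1
        p = (1 + count) / (1 + n_perm)
        return PermTestResult(f_stat, float(p), n_perm, seed, method="betadisper-perm")
    return PermTestResult(f_stat, float(p_param), 0, None, method="betadisper-anova")
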