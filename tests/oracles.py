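"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive re-derivations (loops, exhaustive search)
kept separate from the library code paths they check.
"""

from __future__ import annotations

import numpy as np

UNAMBIGUOUS = set("ACGT")


def brute_ward_merges(points: np.ndarray) -> list[tuple[frozenset, float]]:
    """Greedy minimal-variance-increase agglomeration from raw points.

    Merge cost is sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||
    (the Ward-2D height); returns (merged member set, height) per step.
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    merges: list[tuple[frozenset, float]] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A, B = clusters[a], clusters[b]
                ca = points[list(A)].mean(axis=0)
                cb = points[list(B)].mean(axis=0)
                cost = np.sqrt(2.0 * len(A) * len(B) / (len(A) + len(B))) * float(
                    np.linalg.norm(ca - cb)
                )
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        assert best is not None
        cost, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((merged, cost))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def dp_min_bins(masses: np.ndarray, spectra: np.ndarray, tol: float) -> int:
    """Minimum number of bins over all contiguous partitions of the sorted
    masses satisfying the relative-spread and unique-spectrum constraints."""
    m = np.asarray(masses, dtype=float)
    order = np.argsort(m)
    m = m[order]
    s = np.asarray(spectra)[order]
    n = m.size

    def feasible(i: int, j: int) -> bool:
        seg = m[i:j]
        if (seg[-1] - seg[0]) / seg.mean() > tol:
            return False
        return len(set(s[i:j].tolist())) == j - i

    inf = 10**9
    best = [inf] * (n + 1)
    best[0] = 0
    for j in range(1, n + 1):
        for i in range(j):
            if best[i] + 1 < best[j] and feasible(i, j):
                best[j] = best[i] + 1
    return best[n]


def naive_snip(y: np.ndarray, iterations: int) -> np.ndarray:
    """Plain-loop SNIP clipping, decreasing window, interior points only."""
    b = np.asarray(y, dtype=float).copy()
    n = b.size
    for k in range(min(iterations, (n - 1) // 2), 0, -1):
        prev = b.copy()
        for i in range(k, n - k):
            mid = 0.5 * (prev[i - k] + prev[i + k])
            if mid < b[i]:
                b[i] = mid
    return b


def brute_strict_maxima(x: np.ndarray, half_window: int) -> list[int]:
    """Indices strictly greater than every other point within the window."""
    n = x.size
    out = []
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        if all(x[i] > x[j] for j in range(lo, hi) if j != i):
            out.append(i)
    return out


def unambiguous_columns(sequences: list[str]) -> list[int]:
    """Columns where every sequence holds an unambiguous A/C/G/T."""
    length = len(sequences[0])
    cols = []
    for j in range(length):
        if all(seq[j] in UNAMBIGUOUS for seq in sequences):
            cols.append(j)
    return cols


def match_fraction(masses_a, masses_b, tol: float) -> float:
    """Greedy pairwise mass matching within relative tolerance."""
    a = sorted(masses_a)
    b = list(sorted(masses_b))
    matched = 0
    for m in a:
        best_j, best_rel = None, tol
        for j, x in enumerate(b):
            rel = abs(x - m) / m
            if rel <= best_rel:
                best_j, best_rel = j, rel
        if best_j is not None:
            b.pop(best_j)
            matched += 1
    return matched / min(len(masses_a), len(masses_b))


def scipy_linkage_merges(z: np.ndarray, n: int) -> list[tuple[frozenset, float]]:
    """(member set, height) per linkage row."""
    members = [frozenset([i]) for i in range(n)]
    out = []
    for row in z:
        merged = members[int(row[0])] | members[int(row[1])]
        members.append(merged)
        out.append((merged, float(row[2])))
    return out
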