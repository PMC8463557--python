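"""Peak binning across spectra and the binned feature matrix.

Pooled peak masses are partitioned into bins by recursive largest-gap
splitting under a relative mass tolerance, bins become feature-matrix
columns, low-occupancy columns are dropped, and rows are Hellinger
transformed before any statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectrum import PeakList

__all__ = [
    "BinningResult",
    "FeatureMatrix",
    "bin_peaks",
    "build_feature_matrix",
    "hellinger",
    "peak_patterns",
]


@dataclass
class BinningResult:
    """Outcome of pooled-peak binning.

    ``peaklists`` carry bin-mean masses; ``assignments[i][k]`` is the bin
    index of peak ``k`` of spectrum ``i`` (in the original peak order).
    """

    peaklists: list[PeakList]
    bin_masses: np.ndarray
    assignments: list[np.ndarray]


def bin_peaks(peaklists: Sequence[PeakList], tolerance_rel: float = 0.001) -> BinningResult:
    """Bin peak masses pooled over spectra.

    The sorted pooled masses are split recursively at the largest internal
    gap until every bin satisfies both constraints: relative spread
    ``(max - min) / mean <= tolerance_rel`` and no two peaks from the same
    spectrum. Each peak's mass is then replaced by its bin mean.
    """
    if len(peaklists) < 1:
        raise ValueError("need at least one peak list")
    if tolerance_rel <= 0:
        raise ValueError("tolerance_rel must be positive")

    masses = np.concatenate([pl.masses for pl in peaklists]) if peaklists else np.array([])
    spectrum_idx = np.concatenate(
        [np.full(len(pl), i, dtype=int) for i, pl in enumerate(peaklists)]
    )
    peak_idx = np.concatenate([np.arange(len(pl), dtype=int) for pl in peaklists])
    order = np.argsort(masses, kind="stable")
    m_sorted = masses[order]
    s_sorted = spectrum_idx[order]

    segments = _recursive_split(m_sorted, s_sorted, tolerance_rel)

    bin_masses = np.array([m_sorted[i:j].mean() for i, j in segments])
    bin_of_sorted = np.empty(m_sorted.size, dtype=int)
    for b, (i, j) in enumerate(segments):
        bin_of_sorted[i:j] = b

    assignments = [np.full(len(pl), -1, dtype=int) for pl in peaklists]
    for pos_sorted, b in enumerate(bin_of_sorted):
        orig = order[pos_sorted]
        assignments[spectrum_idx[orig]][peak_idx[orig]] = b

    binned: list[PeakList] = []
    for i, pl in enumerate(peaklists):
        if len(pl) == 0:
            binned.append(pl)
            continue
        new_masses = bin_masses[assignments[i]]
        reorder = np.argsort(new_masses, kind="stable")
        binned.append(
            PeakList(new_masses[reorder], pl.intensities[reorder], pl.snr[reorder], dict(pl.meta))
        )
    return BinningResult(binned, bin_masses, assignments)


def _recursive_split(
    m: np.ndarray, spec: np.ndarray, tol: float
) -> list[tuple[int, int]]:
    """Largest-gap recursive split of sorted masses; returns [start, stop) pairs."""
    out: list[tuple[int, int]] = []
    stack = [(0, m.size)]
    while stack:
        i, j = stack.pop()
        if j - i <= 1:
            out.append((i, j))
            continue
        seg = m[i:j]
        spread_ok = (seg[-1] - seg[0]) / seg.mean() <= tol
        unique_ok = np.unique(spec[i:j]).size == (j - i)
        if spread_ok and unique_ok:
            out.append((i, j))
            continue
        gaps = np.diff(seg)
        cut = i + 1 + int(np.argmax(gaps))  # ties -> first largest gap
        stack.append((cut, j))
        stack.append((i, cut))
    out.sort()
    return out


@dataclass
class FeatureMatrix:
    """Spectra-by-bins intensity table (0 marks an absent peak)."""

    ids: list[str]
    labels: list[str]
    bin_masses: np.ndarray
    values: np.ndarray
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bin_masses = np.asarray(self.bin_masses, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids/labels length must match the number of rows")
        if self.bin_masses.size != p:
            raise ValueError("bin_masses length must match the number of columns")
        if self.bin_masses.size > 1 and np.any(np.diff(self.bin_masses) <= 0):
            raise ValueError("bin masses must be strictly increasing with no duplicates")
        if np.any(self.values < 0):
            raise ValueError("feature values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{m:.2f}" for m in self.bin_masses])
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: id, label, then one column per bin mass (2 dp)."""
        path = Path(path)
        with open(path, "w") as fh:
            for line in self.comments:
                fh.write(f"# {line}\n")
            fh.write("id,label," + ",".join(f"{m:.2f}" for m in self.bin_masses) + "\n")
            for i in range(self.values.shape[0]):
                row = ",".join(repr(float(v)) for v in self.values[i])
                fh.write(f"{self.ids[i]},{self.labels[i]},{row}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        comments: list[str] = []
        with open(path) as fh:
            lines = fh.readlines()
        data_lines = []
        for line in lines:
            if line.startswith("#"):
                comments.append(line.lstrip("#").strip())
            else:
                data_lines.append(line)
        header = data_lines[0].rstrip("\n").split(",")
        bin_masses = np.array([float(h) for h in header[2:]])
        ids, labels, rows = [], [], []
        for line in data_lines[1:]:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(",")
            ids.append(parts[0])
            labels.append(parts[1])
            rows.append([float(v) for v in parts[2:]])
        return cls(ids, labels, bin_masses, np.array(rows), comments)

    def select_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureMatrix(
            [self.ids[i] for i in idx],
            [self.labels[i] for i in idx],
            self.bin_masses.copy(),
            self.values[idx],
            list(self.comments),
        )


def build_feature_matrix(
    binning: BinningResult,
    min_frequency: float = 0.05,
    ids: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Assemble the spectra x bins matrix and drop rare columns.

    A column is kept when the fraction of spectra containing its peak is
    at least ``min_frequency`` (closed boundary). Missing peaks are 0.
    """
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must lie in (0, 1]")
    pls = binning.peaklists
    n = len(pls)
    p = binning.bin_masses.size
    values = np.zeros((n, p))
    present = np.zeros((n, p), dtype=bool)
    for i, pl in enumerate(pls):
        cols = binning.assignments[i]
        # original (pre-binning) intensity order matches assignments
        values[i, cols] = _original_intensities(pl, binning, i)
        present[i, cols] = True
    occupancy = present.mean(axis=0)
    keep = occupancy >= min_frequency
    if not keep.any():
        raise ValueError(
            f"all {p} feature columns fall below the minimum frequency {min_frequency}"
        )
    if ids is None:
        ids = [pl.meta.get("spectrum_id", f"spectrum_{i:04d}") for i, pl in enumerate(pls)]
    if labels is None:
        labels = [str(pl.meta.get("label", "")) for pl in pls]
    return FeatureMatrix(list(ids), list(labels), binning.bin_masses[keep], values[:, keep])


def _original_intensities(pl: PeakList, binning: BinningResult, i: int) -> np.ndarray:
    """Intensities in original peak order (binned peaklists are re-sorted)."""
    cols = binning.assignments[i]
    # the binned peak list is sorted by bin mass; map back via bin index order
    sorted_cols = np.argsort(binning.bin_masses[cols], kind="stable")
    inv = np.empty_like(sorted_cols)
    inv[sorted_cols] = np.arange(sorted_cols.size)
    return pl.intensities[inv]


def hellinger(m: FeatureMatrix) -> FeatureMatrix:
    """Hellinger transform: ``x_ij <- sqrt(x_ij / sum_j x_ij)`` per row."""
    sums = m.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise ValueError(f"all-zero feature row for spectrum '{m.ids[bad[0]]}'")
    values = np.sqrt(m.values / sums[:, None])
    return FeatureMatrix(list(m.ids), list(m.labels), m.bin_masses.copy(), values, list(m.comments))


def peak_patterns(m: FeatureMatrix, pattern_min_frequency: float = 0.8) -> pd.DataFrame:
    """Per-species peak occupancy table, simplified and variance-ordered.

    Rows are species, columns are bin masses. A column is retained only if
    its occupancy reaches ``pattern_min_frequency`` within at least one
    species; retained columns are ordered by decreasing between-species
    occupancy variance.
    """
    if not 0 < pattern_min_frequency <= 1:
        raise ValueError("pattern_min_frequency must lie in (0, 1]")
    present = pd.DataFrame(m.values > 0, columns=[f"{x:.2f}" for x in m.bin_masses])
    present["__label"] = m.labels
    occ = present.groupby("__label", sort=True).mean()
    occ.index.name = "species"
    keep = occ.max(axis=0) >= pattern_min_frequency
    occ = occ.loc[:, keep]
    variance = occ.var(axis=0, ddof=0)
    order = variance.sort_values(ascending=False, kind="stable").index
    return occ.loc[:, order]
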