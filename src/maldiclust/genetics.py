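"""Kimura 2-parameter distances with complete deletion.

Transitions are A<->G and C<->T; everything else among {A,C,G,T} is a
transversion. With transition proportion P and transversion proportion Q,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Complete deletion removes every alignment column that contains a gap,
``N`` or any IUPAC ambiguity code in any sequence; ``U`` is read as ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .distance import DistanceMatrix

__all__ = [
    "Alignment",
    "read_alignment",
    "complete_deletion",
    "k2p_distance",
    "k2p_matrix",
    "write_lower_triangle",
]

_UNAMBIGUOUS = frozenset("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class Alignment:
    """Equal-length nucleotide sequences (uppercase, U mapped to T)."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must have equal length")
        if not self.sequences:
            raise ValueError("alignment is empty")
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]
        length = len(self.sequences[0])
        if length < 1:
            raise ValueError("alignment length must be >= 1")
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise ValueError(
                    f"sequence '{sid}' has length {len(seq)}, expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def complete_deletion(a: Alignment) -> Alignment:
    """Drop every column holding a gap/N/ambiguity in any sequence."""
    arr = np.array([list(s) for s in a.sequences])
    ok = np.isin(arr, list(_UNAMBIGUOUS)).all(axis=0)
    if not ok.any():
        raise ValueError("no unambiguous columns remain after complete deletion")
    kept = ["".join(row) for row in arr[:, ok]]
    return Alignment(list(a.ids), kept)


def pair_counts(s1: str, s2: str) -> tuple[int, float, float]:
    """(n_sites, transition proportion P, transversion proportion Q)."""
    if len(s1) != len(s2):
        raise ValueError("sequences must have equal length")
    n = len(s1)
    if n < 1:
        raise ValueError("need at least one site")
    transitions = transversions = 0
    for x, y in zip(s1, s2):
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    return n, transitions / n, transversions / n


def k2p_distance(s1: str, s2: str) -> float:
    """K2P distance of two gap-free, equal-length sequences."""
    n, p, q = pair_counts(s1, s2)
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        raise ValueError(
            f"K2P distance undefined (saturation): P={p:.4f}, Q={q:.4f}"
        )
    return float(-0.5 * np.log(arg1 * np.sqrt(arg2)))


def k2p_matrix(a: Alignment) -> DistanceMatrix:
    """Pairwise K2P distances after one complete-deletion pass."""
    if len(a) < 2:
        raise ValueError("need at least 2 sequences")
    clean = complete_deletion(a)
    n = len(clean)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(clean.sequences[i], clean.sequences[j])
    return DistanceMatrix(list(clean.ids), d, metric="k2p")


def write_lower_triangle(d: DistanceMatrix, path: str | Path, decimals: int = 4) -> None:
    """Lower-triangle text layout as used by common phylogenetics software."""
    with open(Path(path), "w") as fh:
        fh.write(f"{d.n}\n")
        for i in range(d.n):
            cells = "\t".join(f"{d.data[i, j]:.{decimals}f}" for j in range(i))
            fh.write(f"{d.ids[i]}\t{cells}\n" if cells else f"{d.ids[i]}\n")
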