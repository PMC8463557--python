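"""Core spectrum containers and the plain-text spectrum dialect.

A raw spectrum is a pair of equal-length arrays (m/z in Da, intensity in
arbitrary units) on a strictly increasing mass axis, plus free-form metadata.
Spectra are exchanged as two-column ASCII text with optional ``#`` header
lines; ``# key=value`` headers round-trip into the metadata dict.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RawSpectrum", "PeakList", "read_spectrum", "write_spectrum"]


@dataclass
class RawSpectrum:
    """One measured or simulated mass spectrum.

    Parameters
    ----------
    mass : ndarray
        m/z values in Da, strictly increasing, length >= 2.
    intensity : ndarray
        Intensities in arbitrary units, same length as ``mass``.
    meta : dict
        Provenance metadata (e.g. ``label``, ``station``, ``year``).
    """

    mass: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mass.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mass and intensity must be 1-D arrays")
        if self.mass.shape != self.intensity.shape:
            raise ValueError(
                f"mass and intensity lengths differ: {self.mass.size} != {self.intensity.size}"
            )
        if self.mass.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.mass)):
            raise ValueError("non-finite m/z values")
        if np.any(np.diff(self.mass) <= 0):
            raise ValueError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return self.mass.size

    def with_intensity(self, intensity: np.ndarray) -> "RawSpectrum":
        """Return a copy carrying ``intensity`` on the same mass axis."""
        return RawSpectrum(self.mass.copy(), np.asarray(intensity, dtype=float), dict(self.meta))

    @property
    def label(self) -> str | None:
        return self.meta.get("label")


@dataclass
class PeakList:
    """Detected peak apices for one spectrum.

    ``snr`` is apex intensity divided by the spectrum-wide noise estimate;
    every retained peak satisfies the detection threshold.
    """

    masses: np.ndarray
    intensities: np.ndarray
    snr: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if not (self.masses.shape == self.intensities.shape == self.snr.shape):
            raise ValueError("masses, intensities and snr must have equal length")
        if self.masses.size > 1 and np.any(np.diff(self.masses) <= 0):
            raise ValueError("peak masses must be strictly increasing")

    def __len__(self) -> int:
        return self.masses.size


def read_spectrum(path: str | Path) -> RawSpectrum:
    """Read a two-column ASCII spectrum (whitespace or tab separated).

    Lines starting with ``#`` are headers; ``# key=value`` lines populate the
    metadata dict. Non-monotone m/z axes are rejected.
    """
    path = Path(path)
    meta: dict = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = _coerce(value.strip())
                continue
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"no data rows in {path}")
    arr = np.loadtxt(io.StringIO("\n".join(data_lines)), dtype=float)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise ValueError(f"expected 2 columns in {path}, got {arr.shape[1]}")
    return RawSpectrum(arr[:, 0], arr[:, 1], meta)


def write_spectrum(spectrum: RawSpectrum, path: str | Path) -> None:
    """Write a spectrum in the two-column ASCII dialect with metadata headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}={value}\n")
        for m, i in zip(spectrum.mass, spectrum.intensity):
            fh.write(f"{float(m)!r} {float(i)!r}\n")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value
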