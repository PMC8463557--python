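"""Synthetic MALDI-ToF spectrum generator.

Produces labeled raw spectra with the structure the downstream analysis
assumes: species-specific reproducible peak fingerprints, per-individual
intensity variation and mass jitter, a smooth decaying baseline, and additive
noise truncated at zero.

Peak profiles are Gaussian on an even m/z grid; peak heights vary
multiplicatively (log-normal with configurable coefficient of variation) and
each peak appears per spectrum with a Bernoulli occurrence probability.
The default variation magnitudes are assumptions, not measured values, and
are all exposed on :class:`SimulationConfig`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectrum import RawSpectrum, write_spectrum

__all__ = [
    "SpeciesFingerprint",
    "SimulationConfig",
    "generate_fingerprints",
    "simulate_spectrum",
    "simulate_dataset",
    "write_dataset",
    "shared_peak_fraction",
]


@dataclass(frozen=True)
class SpeciesFingerprint:
    """Ground-truth peak model for one synthetic species."""

    species_label: str
    peak_masses: np.ndarray
    peak_mean_intensities: np.ndarray
    peak_occurrence_probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_masses", np.asarray(self.peak_masses, dtype=float))
        object.__setattr__(
            self, "peak_mean_intensities", np.asarray(self.peak_mean_intensities, dtype=float)
        )
        object.__setattr__(
            self, "peak_occurrence_probs", np.asarray(self.peak_occurrence_probs, dtype=float)
        )
        n = self.peak_masses.size
        if not (self.peak_mean_intensities.size == n == self.peak_occurrence_probs.size):
            raise ValueError("fingerprint arrays must have equal length")
        if n < 1:
            raise ValueError("fingerprint needs at least one peak")
        if np.any(np.diff(self.peak_masses) <= 0):
            raise ValueError("peak masses must be strictly increasing")
        if np.any(self.peak_mean_intensities <= 0):
            raise ValueError("peak mean intensities must be positive")
        if np.any((self.peak_occurrence_probs < 0) | (self.peak_occurrence_probs > 1)):
            raise ValueError("occurrence probabilities must lie in [0, 1]")

    @property
    def n_peaks(self) -> int:
        return self.peak_masses.size


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the spectrum simulator.

    Defaults are chosen so that, after the standard preprocessing chain,
    fingerprint peaks clear an SNR-6 detection threshold comfortably while
    the spectrum still carries a visible baseline hump and noise floor.
    """

    mass_range: tuple[float, float] = (1500.0, 20000.0)
    grid_step: float = 1.0
    peak_width: float = 3.0  # Gaussian sigma, Da
    baseline_amplitude: float = 20.0
    baseline_decay: float = 3.0e-4  # 1/Da
    noise_sd: float = 0.5
    mass_jitter_rel: float = 1.0e-4
    intensity_cv: float = 0.25
    intensity_range: tuple[float, float] = (30.0, 120.0)
    min_peak_separation: float = 30.0  # Da, within one fingerprint
    edge_margin: float = 100.0  # Da, keep peaks off the range ends
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.mass_range
        if not low < high:
            raise ValueError("mass_range low must be < high")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be >= 0")
        if self.mass_jitter_rel < 0:
            raise ValueError("mass_jitter_rel must be >= 0")
        if self.baseline_amplitude < 0:
            raise ValueError("baseline_amplitude must be >= 0")

    def grid(self) -> np.ndarray:
        low, high = self.mass_range
        n = int(np.floor((high - low) / self.grid_step)) + 1
        return low + self.grid_step * np.arange(n)


def shared_peak_fraction(masses_a: np.ndarray, masses_b: np.ndarray, tolerance_rel: float) -> float:
    """Fraction of the smaller fingerprint matched by the other within a
    relative mass tolerance (greedy nearest matching)."""
    a = np.sort(np.asarray(masses_a, dtype=float))
    b = np.sort(np.asarray(masses_b, dtype=float))
    used = np.zeros(b.size, dtype=bool)
    matched = 0
    for m in a:
        rel = np.abs(b - m) / m
        rel[used] = np.inf
        j = int(np.argmin(rel))
        if rel[j] <= tolerance_rel:
            used[j] = True
            matched += 1
    return matched / min(a.size, b.size)


def generate_fingerprints(
    n_species: int,
    n_peaks_range: tuple[int, int],
    config: SimulationConfig,
    rng_seed: int,
    *,
    max_overlap: float = 0.2,
    tolerance_rel: float = 0.001,
    max_tries: int = 200,
    labels: Sequence[str] | None = None,
) -> list[SpeciesFingerprint]:
    """Draw pairwise-distinct species fingerprints.

    Each species gets ``n_peaks`` masses (uniform in ``n_peaks_range``)
    placed uniformly inside the mass range with a minimum mutual separation;
    candidates are re-drawn until no pair of species shares more than
    ``max_overlap`` of its peaks within ``tolerance_rel``.

    Raises
    ------
    ValueError
        If the constraints are infeasible (too many peaks for the range at
        the required separation) or ``max_tries`` redraws are exhausted.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    lo, hi = n_peaks_range
    if lo < 1 or hi < lo:
        raise ValueError("n_peaks_range must satisfy 1 <= min <= max")
    low, high = config.mass_range
    usable = (high - config.edge_margin) - (low + config.edge_margin)
    if usable <= 0 or (hi - 1) * config.min_peak_separation > usable:
        raise ValueError(
            f"cannot place {hi} peaks separated by {config.min_peak_separation} Da "
            f"in a usable range of {usable:.1f} Da"
        )
    if labels is not None and len(labels) != n_species:
        raise ValueError("labels length must equal n_species")

    rng = np.random.default_rng(rng_seed)
    fingerprints: list[SpeciesFingerprint] = []
    for i in range(n_species):
        n_peaks = int(rng.integers(lo, hi + 1))
        for _ in range(max_tries):
            masses = _draw_masses(rng, n_peaks, config)
            ok = all(
                shared_peak_fraction(masses, fp.peak_masses, tolerance_rel) <= max_overlap
                for fp in fingerprints
            )
            if ok:
                break
        else:
            raise ValueError(
                f"could not draw a fingerprint for species {i} with pairwise "
                f"overlap <= {max_overlap} after {max_tries} tries"
            )
        lo_i, hi_i = config.intensity_range
        intensities = rng.uniform(lo_i, hi_i, size=n_peaks)
        probs = rng.uniform(0.7, 1.0, size=n_peaks)
        label = labels[i] if labels is not None else f"species_{i:02d}"
        fingerprints.append(SpeciesFingerprint(label, masses, intensities, probs))
    return fingerprints


def _draw_masses(rng: np.random.Generator, n_peaks: int, config: SimulationConfig) -> np.ndarray:
    """Uniform masses with a minimum mutual separation, via spacing trick."""
    low = config.mass_range[0] + config.edge_margin
    high = config.mass_range[1] - config.edge_margin
    sep = config.min_peak_separation
    # subtract the mandatory gaps, draw order statistics, re-add the gaps
    slack = (high - low) - (n_peaks - 1) * sep
    u = np.sort(rng.uniform(0.0, slack, size=n_peaks))
    return low + u + sep * np.arange(n_peaks)


def simulate_spectrum(
    fp: SpeciesFingerprint,
    config: SimulationConfig,
    rng_seed: int | np.random.Generator,
) -> RawSpectrum:
    """Simulate one raw spectrum from a species fingerprint.

    intensity = baseline + sum of present Gaussian peaks + truncated noise,
    with per-spectrum Bernoulli peak occurrence, relative mass jitter and
    log-normal (mean-preserving) height variation.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    grid = config.grid()
    low = config.mass_range[0]
    baseline = config.baseline_amplitude * np.exp(-config.baseline_decay * (grid - low))

    n = fp.n_peaks
    # fixed draw order keeps spectra bit-reproducible under a seed
    present = rng.random(n) < fp.peak_occurrence_probs
    jitter = rng.normal(0.0, config.mass_jitter_rel, size=n) if config.mass_jitter_rel > 0 else np.zeros(n)
    if config.intensity_cv > 0:
        sigma2 = np.log1p(config.intensity_cv**2)
        heights = fp.peak_mean_intensities * rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=n)
    else:
        heights = fp.peak_mean_intensities.copy()
        rng.lognormal(0.0, 1.0, size=n)  # burn draws so presence/jitter streams stay aligned

    intensity = baseline.copy()
    width = config.peak_width
    for j in range(n):
        if not present[j]:
            continue
        mu = fp.peak_masses[j] * (1.0 + jitter[j])
        lo_idx, hi_idx = np.searchsorted(grid, [mu - 8 * width, mu + 8 * width])
        window = grid[lo_idx:hi_idx]
        intensity[lo_idx:hi_idx] += heights[j] * np.exp(-0.5 * ((window - mu) / width) ** 2)

    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=grid.size)
    intensity = np.maximum(intensity, 0.0)
    meta = {"label": fp.species_label}
    return RawSpectrum(grid, intensity, meta)


def simulate_dataset(
    fps: Sequence[SpeciesFingerprint],
    n_per_species: Sequence[int],
    config: SimulationConfig,
    seed: int,
) -> list[RawSpectrum]:
    """Simulate ``n_per_species[i]`` spectra from each fingerprint.

    Per-spectrum RNG streams are spawned from a single seed, so the dataset
    is reproducible as a whole and per spectrum.
    """
    if len(fps) != len(n_per_species):
        raise ValueError(
            f"got {len(fps)} fingerprints but {len(n_per_species)} counts"
        )
    if any(c < 1 for c in n_per_species):
        raise ValueError("all per-species counts must be >= 1")
    total = int(sum(n_per_species))
    children = np.random.SeedSequence(seed).spawn(total)
    spectra: list[RawSpectrum] = []
    idx = 0
    for fp, count in zip(fps, n_per_species):
        for rep in range(count):
            rng = np.random.default_rng(children[idx])
            s = simulate_spectrum(fp, config, rng)
            s.meta["replicate"] = rep
            s.meta["spectrum_id"] = f"{fp.species_label}_{rep:03d}"
            spectra.append(s)
            idx += 1
    return spectra


def write_dataset(spectra: Sequence[RawSpectrum], outdir: str | Path, seed: int | None = None) -> Path:
    """Write spectra as ASCII files plus a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "species_label", "seed"])
        for i, s in enumerate(spectra):
            name = f"spectrum_{i:04d}.txt"
            write_spectrum(s, outdir / name)
            writer.writerow([name, s.meta.get("label", ""), "" if seed is None else seed])
    return manifest
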