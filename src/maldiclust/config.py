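"""Flat pipeline configuration with YAML round-trip.

Defaults reproduce the published parameter set: 1.5-20 kDa trim, SNR 6,
peak half-window 7, binning tolerance 0.001, minimum frequency 0.05,
Ward-2D on Euclidean distances with 10,000 bootstrap replications per
scale, Bray-Curtis NMDS with k = 2, 999 permutations, and a 0.8 pattern
frequency.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cluster import MultiscaleBootstrapParams
from .preprocess import ProcessingParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocessing / feature extraction
    sqrt_transform: bool = True
    sg_half_window: int = 10
    sg_polyorder: int = 3
    snip_iterations: int = 100
    tic_target: float = 1.0
    trim_low: float = 1500.0
    trim_high: float = 20000.0
    snr_threshold: float = 6.0
    peak_half_window: int = 7
    bin_tolerance_rel: float = 0.001
    min_frequency: float = 0.05
    pattern_min_frequency: float = 0.8
    # clustering / bootstrap
    bootstrap_scales: list[float] = field(
        default_factory=lambda: [round(0.5 + 0.1 * i, 1) for i in range(10)]
    )
    bootstrap_replicates: int = 10_000
    # ordination
    nmds_k: int = 2
    nmds_restarts: int = 8
    nmds_distance: str = "braycurtis"  # or "euclidean"
    # permutation tests
    n_permutations: int = 999
    # ranking
    dda_on_hellinger: bool = True
    # misc
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def processing_params(self) -> ProcessingParams:
        return ProcessingParams(
            sqrt_transform=self.sqrt_transform,
            sg_half_window=self.sg_half_window,
            sg_polyorder=self.sg_polyorder,
            snip_iterations=self.snip_iterations,
            tic_target=self.tic_target,
            trim_range=(self.trim_low, self.trim_high),
            snr_threshold=self.snr_threshold,
            peak_half_window=self.peak_half_window,
            bin_tolerance_rel=self.bin_tolerance_rel,
            min_frequency=self.min_frequency,
            pattern_min_frequency=self.pattern_min_frequency,
        )

    def bootstrap_params(self, seed: int) -> MultiscaleBootstrapParams:
        return MultiscaleBootstrapParams(
            scales=tuple(self.bootstrap_scales),
            replicates_per_scale=self.bootstrap_replicates,
            seed=seed,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Short stable hash of the analysis parameters (paths excluded)."""
        data = asdict(self)
        data.pop("input_dir", None)
        data.pop("output_dir", None)
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
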