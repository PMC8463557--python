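"""Raw-spectrum preprocessing: trim, variance stabilisation, smoothing,
SNIP baseline removal, TIC normalisation, and SNR-based peak detection.

The fixed stage order is trim -> sqrt -> Savitzky-Golay smoothing -> SNIP
baseline removal -> TIC normalisation -> noise estimation / peak picking;
:func:`preprocess` runs the chain up to (not including) peak picking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_filter

from .spectrum import PeakList, RawSpectrum

__all__ = [
    "ProcessingParams",
    "trim_range",
    "sqrt_transform",
    "smooth_sg",
    "snip_baseline",
    "remove_baseline",
    "tic_normalize",
    "estimate_noise",
    "detect_peaks",
    "preprocess",
]

MAD_SCALE = 1.4826  # makes the MAD consistent for the normal distribution


@dataclass(frozen=True)
class ProcessingParams:
    """Parameters of the preprocessing and feature-extraction chain.

    Defaults follow the published analysis: 1.5-20 kDa trim, SNR 6 with a
    peak half-window of 7 points, relative binning tolerance 0.001, minimum
    bin occupancy 0.05, and a 0.8 occupancy threshold for the per-species
    peak-pattern table. Smoothing window and SNIP iteration count are
    workflow conventions (unstated in the source) and are exposed here.
    """

    sqrt_transform: bool = True
    sg_half_window: int = 10
    sg_polyorder: int = 3
    snip_iterations: int = 100
    tic_target: float = 1.0
    trim_range: tuple[float, float] = (1500.0, 20000.0)
    snr_threshold: float = 6.0
    peak_half_window: int = 7
    bin_tolerance_rel: float = 0.001
    min_frequency: float = 0.05
    pattern_min_frequency: float = 0.8

    def __post_init__(self) -> None:
        if self.sg_half_window < 1 or self.sg_polyorder < 0:
            raise ValueError("invalid Savitzky-Golay parameters")
        if 2 * self.sg_half_window + 1 <= self.sg_polyorder:
            raise ValueError("SG window must exceed the polynomial order")
        if self.snip_iterations < 1:
            raise ValueError("snip_iterations must be >= 1")
        if self.tic_target <= 0:
            raise ValueError("tic_target must be positive")
        if not self.trim_range[0] < self.trim_range[1]:
            raise ValueError("trim_range low must be < high")
        if self.snr_threshold <= 0 or self.peak_half_window < 1:
            raise ValueError("invalid peak detection parameters")
        if self.bin_tolerance_rel <= 0:
            raise ValueError("bin_tolerance_rel must be positive")
        for name in ("min_frequency", "pattern_min_frequency"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


def trim_range(s: RawSpectrum, mass_range: tuple[float, float]) -> RawSpectrum:
    """Keep only points with ``low <= m/z <= high``."""
    low, high = mass_range
    if not low < high:
        raise ValueError("trim range low must be < high")
    mask = (s.mass >= low) & (s.mass <= high)
    if mask.sum() < 2:
        raise ValueError(f"empty spectrum after trimming to [{low}, {high}] Da")
    return RawSpectrum(s.mass[mask], s.intensity[mask], dict(s.meta))


def sqrt_transform(s: RawSpectrum) -> RawSpectrum:
    if np.any(s.intensity < 0):
        raise ValueError("cannot sqrt-transform negative intensities")
    return s.with_intensity(np.sqrt(s.intensity))


def smooth_sg(s: RawSpectrum, half_window: int = 10, polyorder: int = 3) -> RawSpectrum:
    """Savitzky-Golay smoothing with window ``2 * half_window + 1``."""
    window = 2 * half_window + 1
    if window <= polyorder:
        raise ValueError("window must exceed polynomial order")
    if window > len(s):
        raise ValueError(f"window {window} larger than spectrum of {len(s)} points")
    return s.with_intensity(savgol_filter(s.intensity, window, polyorder, mode="interp"))


def snip_baseline(s: RawSpectrum, iterations: int = 100) -> np.ndarray:
    """SNIP baseline estimate (iterative min-clipping, decreasing window).

    For clipping half-window k the update is
    ``b(i) <- min(b(i), (b(i-k) + b(i+k)) / 2)`` applied to all interior
    points; k runs from ``iterations`` down to 1 (the decreasing-window
    finishing order), with spectrum edges left clamped to the input.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    b = s.intensity.astype(float).copy()
    n = b.size
    for k in range(min(iterations, (n - 1) // 2), 0, -1):
        mid = 0.5 * (b[: n - 2 * k] + b[2 * k :])
        b[k : n - k] = np.minimum(b[k : n - k], mid)
    return b


def remove_baseline(s: RawSpectrum, baseline: np.ndarray) -> RawSpectrum:
    """Subtract a baseline, clipping negative residuals to zero."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensity.shape:
        raise ValueError(
            f"baseline length {baseline.size} does not match spectrum length {len(s)}"
        )
    return s.with_intensity(np.maximum(s.intensity - baseline, 0.0))


def tic_normalize(s: RawSpectrum, target: float = 1.0) -> RawSpectrum:
    """Scale intensities so their sum (total ion current) equals ``target``."""
    total = float(s.intensity.sum())
    if total <= 0:
        raise ValueError("cannot TIC-normalize a spectrum with zero total intensity")
    return s.with_intensity(s.intensity * (target / total))


def estimate_noise(s: RawSpectrum) -> float:
    """Robust noise level: scaled median absolute deviation of intensities."""
    x = s.intensity
    return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))


def detect_peaks(
    s: RawSpectrum,
    snr_threshold: float = 6.0,
    peak_half_window: int = 7,
    noise: float | None = None,
) -> PeakList:
    """Pick strict local maxima over a ``2 * peak_half_window + 1`` window
    whose intensity reaches ``snr_threshold`` times the noise level.

    A point qualifies only if it is strictly greater than every other point
    in its window (plateaus yield no peak). An empty peak list is valid.
    """
    if noise is None:
        noise = estimate_noise(s)
    x = s.intensity
    hw = peak_half_window
    padded = np.pad(x, hw, mode="constant", constant_values=-np.inf)
    windows = sliding_window_view(padded, 2 * hw + 1)
    # strict max: the apex is the only point in its window >= itself
    is_strict_max = (windows >= x[:, None]).sum(axis=1) == 1
    if noise > 0:
        snr = x / noise
    else:
        snr = np.where(x > 0, np.inf, 0.0)
    keep = is_strict_max & (snr >= snr_threshold)
    return PeakList(s.mass[keep], x[keep], snr[keep], dict(s.meta))


def preprocess(s: RawSpectrum, params: ProcessingParams | None = None) -> RawSpectrum:
    """Run trim -> sqrt -> smooth -> SNIP removal -> TIC on one spectrum."""
    params = params or ProcessingParams()
    out = trim_range(s, params.trim_range)
    if params.sqrt_transform:
        out = sqrt_transform(out)
    out = smooth_sg(out, params.sg_half_window, params.sg_polyorder)
    # clip SG undershoot: negative flanks would otherwise drag the SNIP
    # min-filter below zero across the whole spectrum
    out = out.with_intensity(np.maximum(out.intensity, 0.0))
    baseline = snip_baseline(out, params.snip_iterations)
    out = remove_baseline(out, baseline)
    out = tic_normalize(out, params.tic_target)
    return out
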