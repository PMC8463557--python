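import numpy as np
import pytest

from maldiclust import (
    FeatureMatrix,
    ProcessingParams,
    SimulationConfig,
    bin_peaks,
    build_feature_matrix,
    detect_peaks,
    generate_fingerprints,
    hellinger,
    preprocess,
    simulate_dataset,
)

FAST_RANGE = (1500.0, 6000.0)


@pytest.fixture
def fast_config() -> SimulationConfig:
    """Reduced mass range so per-test simulation stays cheap."""
    return SimulationConfig(mass_range=FAST_RANGE, seed=0)


@pytest.fixture
def fast_params() -> ProcessingParams:
    return ProcessingParams(trim_range=FAST_RANGE)


@pytest.fixture
def clean_config() -> SimulationConfig:
    """Noise-free, jitter-free variant for exact-recovery checks."""
    return SimulationConfig(
        mass_range=FAST_RANGE,
        noise_sd=0.0,
        baseline_amplitude=0.0,
        mass_jitter_rel=0.0,
        intensity_cv=0.0,
    )


def feature_matrix_from(values, labels=None, masses=None) -> FeatureMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = [f"s{i}" for i in range(n)]
    labels = labels if labels is not None else ["x"] * n
    masses = masses if masses is not None else 2000.0 + 100.0 * np.arange(p)
    return FeatureMatrix(ids, list(labels), np.asarray(masses, dtype=float), values)


def hellinger_matrix_for(
    n_species: int,
    per_species: int,
    config: SimulationConfig,
    params: ProcessingParams,
    seed: int,
    n_peaks_range=(6, 12),
) -> FeatureMatrix:
    """Simulated dataset pushed through the full preprocessing chain."""
    fps = generate_fingerprints(n_species, n_peaks_range, config, rng_seed=seed)
    spectra = simulate_dataset(fps, [per_species] * n_species, config, seed=seed)
    pls = [
        detect_peaks(preprocess(s, params), params.snr_threshold, params.peak_half_window)
        for s in spectra
    ]
    matrix = build_feature_matrix(bin_peaks(pls, params.bin_tolerance_rel), params.min_frequency)
    return hellinger(matrix)
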