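import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiclust import (
    RawSpectrum,
    detect_peaks,
    estimate_noise,
    preprocess,
    remove_baseline,
    smooth_sg,
    snip_baseline,
    sqrt_transform,
    tic_normalize,
    trim_range,
)
from maldiclust.preprocess import ProcessingParams

from oracles import brute_strict_maxima, naive_snip


def spectrum(mass, intensity, **meta):
    return RawSpectrum(np.asarray(mass, float), np.asarray(intensity, float), meta)


class TestTrimRange:
    def test_trims_to_range(self):
        mass = np.arange(1000.0, 25000.0, 100.0)
        s = spectrum(mass, np.ones_like(mass))
        t = trim_range(s, (1500.0, 20000.0))
        assert t.mass.min() >= 1500.0
        assert t.mass.max() <= 20000.0

    def test_identity_inside_range(self):
        s = spectrum([2000.0, 3000.0, 4000.0], [1.0, 2.0, 3.0], label="a")
        t = trim_range(s, (1500.0, 20000.0))
        assert np.array_equal(t.mass, s.mass)
        assert t.meta["label"] == "a"

    def test_empty_result_error(self):
        s = spectrum(np.linspace(1500.0, 20000.0, 50), np.ones(50))
        with pytest.raises(ValueError, match="empty spectrum"):
            trim_range(s, (30000.0, 40000.0))


class TestSqrtTransform:
    def test_example(self):
        s = spectrum([1.0, 2.0, 3.0], [0.0, 4.0, 9.0])
        assert np.array_equal(sqrt_transform(s).intensity, [0.0, 2.0, 3.0])

    def test_all_zero(self):
        s = spectrum([1.0, 2.0], [0.0, 0.0])
        assert np.array_equal(sqrt_transform(s).intensity, [0.0, 0.0])

    def test_negative_error(self):
        with pytest.raises(ValueError, match="negative"):
            sqrt_transform(spectrum([1.0, 2.0], [1.0, -1.0]))

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=50))
    def test_square_inverts(self, values):
        s = spectrum(np.arange(len(values), dtype=float) + 1.0, values)
        back = sqrt_transform(s).intensity ** 2
        assert np.allclose(back, values, atol=1e-6, rtol=1e-12)


class TestSmoothSG:
    def test_reproduces_cubic(self):
        x = np.arange(200.0)
        y = 1e-4 * x**3 - 0.02 * x**2 + x + 5.0
        out = smooth_sg(spectrum(x + 1000.0, y), half_window=10, polyorder=3)
        interior = slice(10, -10)
        assert np.allclose(out.intensity[interior], y[interior], atol=1e-9)

    def test_constant_unchanged(self):
        s = spectrum(np.arange(100.0), np.full(100, 7.0))
        assert np.allclose(smooth_sg(s).intensity, 7.0)

    def test_white_noise_variance_shrinks(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.0, 1.0, size=10_001)
        out = smooth_sg(spectrum(np.arange(10_001.0), y), half_window=10, polyorder=3)
        assert out.intensity[10:-10].var() < 0.25

    def test_window_too_large(self):
        with pytest.raises(ValueError, match="larger than spectrum"):
            smooth_sg(spectrum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), half_window=10)


class TestSnipBaseline:
    def test_constant_fixed_point(self):
        s = spectrum(np.arange(50.0), np.full(50, 3.0))
        assert np.allclose(snip_baseline(s, 20), 3.0)

    def test_baseline_below_input(self):
        rng = np.random.default_rng(1)
        s = spectrum(np.arange(500.0), rng.uniform(0.0, 10.0, 500))
        b = snip_baseline(s, 100)
        assert np.all(b <= s.intensity + 1e-12)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0.0, 5.0, 120)
        s = spectrum(np.arange(120.0), y)
        for iterations in (1, 3, 17, 60):
            assert np.allclose(snip_baseline(s, iterations), naive_snip(y, iterations))

    def test_ramp_plus_peak_recovered(self):
        n = 1000
        x = np.arange(float(n))
        ramp = 10.0 + 0.01 * x
        peak = 40.0 * np.exp(-0.5 * ((x - 500.0) / 5.0) ** 2)
        s = spectrum(x + 1500.0, ramp + peak)
        b = snip_baseline(s, 100)
        off_peak = np.abs(x - 500.0) > 50.0
        ramp_range = ramp.max() - ramp.min()
        assert np.max(np.abs(b - ramp)[off_peak]) < 0.02 * ramp_range
        residual = remove_baseline(s, b)
        assert residual.intensity[500] == pytest.approx(40.0, rel=0.05)


class TestRemoveBaseline:
    def test_peakless_residual_near_zero(self):
        x = np.arange(300.0)
        s = spectrum(x + 1500.0, 5.0 + 0.01 * x)
        b = snip_baseline(s, 100)
        residual = remove_baseline(s, b)
        assert np.all(residual.intensity >= 0.0)
        assert residual.intensity.max() < 0.15

    def test_zero_baseline_identity(self):
        s = spectrum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.array_equal(remove_baseline(s, np.zeros(3)).intensity, s.intensity)

    def test_length_mismatch(self):
        s = spectrum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="length"):
            remove_baseline(s, np.zeros(4))

    def test_clips_negative(self):
        s = spectrum([1.0, 2.0], [1.0, 1.0])
        assert np.array_equal(remove_baseline(s, np.array([2.0, 0.5])).intensity, [0.0, 0.5])


class TestTicNormalize:
    def test_example(self):
        s = spectrum([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        assert np.allclose(tic_normalize(s, 1.0).intensity, [0.2, 0.3, 0.5])

    def test_equal_totals(self):
        a = tic_normalize(spectrum([1.0, 2.0], [1.0, 9.0]))
        b = tic_normalize(spectrum([1.0, 2.0], [123.0, 4.0]))
        assert a.intensity.sum() == pytest.approx(b.intensity.sum())

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25)
    def test_scale_invariance(self, factor):
        base = spectrum([1.0, 2.0, 3.0], [1.0, 4.0, 2.0])
        scaled = spectrum([1.0, 2.0, 3.0], factor * base.intensity)
        assert np.allclose(
            tic_normalize(base).intensity, tic_normalize(scaled).intensity, rtol=1e-12
        )

    def test_zero_spectrum_error(self):
        with pytest.raises(ValueError, match="zero total"):
            tic_normalize(spectrum([1.0, 2.0], [0.0, 0.0]))


class TestEstimateNoise:
    def test_constant_zero(self):
        assert estimate_noise(spectrum(np.arange(10.0), np.full(10, 4.0))) == 0.0

    def test_alternating_hand_computation(self):
        # median 1, |x - 1| = 1 everywhere, MAD 1 -> 1.4826
        y = np.tile([0.0, 2.0], 50)
        assert estimate_noise(spectrum(np.arange(100.0), y)) == pytest.approx(1.4826)

    def test_gaussian_consistency(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0.0, 2.0, 50_000)
        assert estimate_noise(spectrum(np.arange(50_000.0), y)) == pytest.approx(2.0, rel=0.02)


class TestDetectPeaks:
    def test_single_peak_over_noise_floor(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = np.arange(float(n))
        y = rng.normal(0.0, 1.0, n)
        y += 100.0 * np.exp(-0.5 * ((x - 1000.0) / 3.0) ** 2)
        s = spectrum(x + 1500.0, y)
        pl = detect_peaks(s, snr_threshold=6.0, peak_half_window=7)
        assert len(pl) == 1
        apex = brute_strict_maxima(y, 7)
        high = [i for i in apex if y[i] >= 6.0 * estimate_noise(s)]
        assert [float(s.mass[i]) for i in high] == pl.masses.tolist()

    def test_windowed_maximum_suppresses_neighbor(self):
        n = 200
        y = np.zeros(n)
        y[100] = 10.0
        y[103] = 8.0  # 3 points away, inside the +-7 window of the higher apex
        s = spectrum(np.arange(float(n)) + 1500.0, y + 0.01 * np.sin(np.arange(n)))
        pl = detect_peaks(s, snr_threshold=0.5, peak_half_window=7)
        assert 1600.0 in pl.masses.tolist()
        assert 1603.0 not in pl.masses.tolist()

    def test_pure_noise_yields_no_peaks(self):
        hits = 0
        for rep in range(500):
            rng = np.random.default_rng(rep)
            y = rng.normal(0.0, 1.0, 2000)
            s = spectrum(np.arange(2000.0) + 1500.0, y)
            if len(detect_peaks(s, snr_threshold=6.0, peak_half_window=7)) > 0:
                hits += 1
        assert hits <= 5  # 0 peaks in >= 99% of replicates

    def test_plateau_not_a_peak(self):
        y = np.zeros(100)
        y[40:43] = 5.0
        s = spectrum(np.arange(100.0) + 1500.0, y)
        assert len(detect_peaks(s, snr_threshold=0.1, peak_half_window=7)) == 0

    def test_snr_recorded(self):
        y = np.zeros(100)
        y[50] = 10.0
        y[::2] += 1.0  # gives a nonzero MAD
        s = spectrum(np.arange(100.0) + 1500.0, y)
        pl = detect_peaks(s, snr_threshold=3.0, peak_half_window=7)
        noise = estimate_noise(s)
        assert np.allclose(pl.snr, pl.intensities / noise)


class TestPipelineOrder:
    def test_noise_free_chain_recovers_fingerprint(self, clean_config, fast_params):
        from maldiclust import SpeciesFingerprint, simulate_spectrum

        fp = SpeciesFingerprint(
            "x", [2000.0, 2600.0, 3300.0, 4100.0, 5000.0], [50.0] * 5, [1.0] * 5
        )
        s = simulate_spectrum(fp, clean_config, rng_seed=0)
        q = preprocess(s, fast_params)
        pl = detect_peaks(q, fast_params.snr_threshold, fast_params.peak_half_window)
        assert len(pl) == fp.n_peaks
        assert np.all(np.abs(pl.masses - fp.peak_masses) <= clean_config.grid_step)

    def test_tic_conservation_end_to_end(self, fast_config, fast_params):
        from maldiclust import SpeciesFingerprint, simulate_spectrum

        fp = SpeciesFingerprint("x", [2000.0, 3000.0], [50.0, 70.0], [1.0, 1.0])
        q = preprocess(simulate_spectrum(fp, fast_config, rng_seed=0), fast_params)
        assert q.intensity.sum() == pytest.approx(fast_params.tic_target)


class TestProcessingParams:
    def test_defaults_match_published_values(self):
        p = ProcessingParams()
        assert p.trim_range == (1500.0, 20000.0)
        assert p.snr_threshold == 6.0
        assert p.peak_half_window == 7
        assert p.bin_tolerance_rel == 0.001
        assert p.min_frequency == 0.05
        assert p.pattern_min_frequency == 0.8

    def test_validation(self):
        with pytest.raises(ValueError):
            ProcessingParams(min_frequency=0.0)
        with pytest.raises(ValueError):
            ProcessingParams(sg_half_window=1, sg_polyorder=5)
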