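import numpy as np
import pytest
from scipy.signal import find_peaks

from burstcode.simulator import default_kernels
from burstcode.stimulus import StimulusTrace, generate_uniform_stimulus
from burstcode.triggered import (
    TriggeredAverage,
    amplitude_vs_distance,
    compute_bta,
    deviation_by_phase,
    f16_smooth,
    peak_frequency,
    phase_bin_index,
    rms_deviation,
)


def f16_oracle(x, half=8):
    """Truncated-renormalized boxcar by explicit double loop."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


class TestF16:
    def test_constant_preserved(self):
        assert np.allclose(f16_smooth(np.full(50, 3.7)), 3.7)

    def test_impulse_spreads_to_17_samples(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = f16_smooth(x)
        assert np.allclose(y[42:59], 1 / 17)
        assert np.allclose(y[:42], 0) and np.allclose(y[59:], 0)

    def test_matches_convolution_oracle(self, rng):
        for _ in range(5):
            x = rng.standard_normal(rng.integers(30, 400))
            np.testing.assert_allclose(f16_smooth(x), f16_oracle(x), atol=1e-12)

    def test_sinusoid_attenuation(self, rng):
        # a 30 Hz sinusoid through the boxcar keeps its shape, scaled by the
        # boxcar's transfer value; verified against the direct oracle
        t = np.arange(600)
        x = np.cos(2 * np.pi * 30 * t / 1000)
        np.testing.assert_allclose(f16_smooth(x), f16_oracle(x), atol=1e-12)


class TestBta:
    def test_null_with_random_triggers(self, rng):
        tr = generate_uniform_stimulus(200_000, 30.0, seed=4)
        trig = rng.integers(400, tr.n_samples - 100, 4000).astype(float)
        bta = compute_bta(tr, trig, (-300, 0))
        assert np.abs(bta.values).max() < 5 / np.sqrt(4000)

    def test_recovers_planted_kernel(self):
        # triggers at maxima of the stimulus filtered with a known kernel
        _, f_w1, _ = default_kernels()
        tr = generate_uniform_stimulus(300_000, 30.0, seed=6)
        filt = np.convolve(tr.values, f_w1[::-1], mode="valid")
        peaks, _ = find_peaks(filt, height=2.0 * filt.std(), distance=150)
        trig = (peaks + 300).astype(float)
        bta = compute_bta(tr, trig, (-300, 0))
        r = np.corrcoef(bta.values, f16_smooth(f_w1))[0, 1]
        assert r > 0.9

    def test_linearity_in_stimulus(self, rng):
        v1 = rng.standard_normal(3000)
        v2 = rng.standard_normal(3000)
        trig = rng.integers(400, 2900, 50).astype(float)
        a, b = 2.0, -0.7
        combo = compute_bta(StimulusTrace(a * v1 + b * v2), trig).values
        s1 = compute_bta(StimulusTrace(v1), trig).values
        s2 = compute_bta(StimulusTrace(v2), trig).values
        np.testing.assert_allclose(combo, a * s1 + b * s2, atol=1e-10)

    def test_all_triggers_out_of_range_errors(self):
        tr = generate_uniform_stimulus(2000, 30.0, seed=0)
        with pytest.raises(ValueError):
            compute_bta(tr, np.array([10.0, 50.0]), (-300, 0))


class TestPhaseBins:
    def test_bin_assignment(self):
        # 15 <= 17 < 45 -> bin 1; 350 wraps to bin 0
        assert phase_bin_index(np.array([17.0]))[0] == 1
        assert phase_bin_index(np.array([350.0]))[0] == 0
        assert phase_bin_index(np.array([344.9]))[0] == 11

    def test_weighted_deviations_sum_to_zero(self, rng):
        # deviations are residuals around the grand BTA: their count-weighted
        # sum vanishes when the reference comes from the same bursts
        seqs = rng.standard_normal((240, 326))
        phases = rng.uniform(0, 360, 240)
        _, devs = deviation_by_phase(seqs, phases)
        total = np.zeros(326)
        for d in devs:
            if d is not None:
                total += d.n_triggers * d.values
        assert np.abs(total).max() < 1e-6 * np.abs(seqs).max() * len(seqs)


class TestRms:
    def test_zero_and_constant(self):
        tau = np.arange(-300, 26, dtype=float)
        ta = TriggeredAverage(tau=tau, values=np.zeros_like(tau), n_triggers=5)
        assert rms_deviation(ta) == 0.0
        ta.values[:] = -0.4
        assert rms_deviation(ta) == pytest.approx(0.4)

    def test_window_not_covered_errors(self):
        tau = np.arange(-100, 1, dtype=float)
        ta = TriggeredAverage(tau=tau, values=np.zeros_like(tau), n_triggers=1)
        with pytest.raises(ValueError):
            rms_deviation(ta)


class TestAmplitudeVsDistance:
    def test_flat_null_when_isis_uninformative(self, rng):
        seqs = rng.standard_normal((2000, 326))
        u = rng.standard_normal((2000, 2))
        centers, rms_vals = amplitude_vs_distance(seqs, u[:, 0], u[:, 1])
        # pure estimator noise: amplitudes are small and trendless
        assert rms_vals.max() < 0.15
        assert np.ptp(rms_vals) < 0.05

    def test_single_bin_degenerate_errors(self, rng):
        seqs = rng.standard_normal((30, 326))
        u = np.ones(30)
        with pytest.raises(ValueError):
            amplitude_vs_distance(seqs, u, u, n_bins=1)


class TestPeakFrequency:
    def test_pure_8hz_cosine(self):
        t = np.arange(300)
        w = np.cos(2 * np.pi * 8 * t / 1000)
        assert peak_frequency(w) == pytest.approx(8.0, abs=0.5)

    def test_dc_only_flagged(self):
        with pytest.warns(UserWarning):
            out = peak_frequency(np.full(300, 2.0))
        assert np.isnan(out)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            peak_frequency(np.ones(50))
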