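"""Welch estimator against a direct transcription of its defining sums."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivevitals.spectral import (
    BandPower,
    WelchSpec,
    band_power,
    drowsiness_score,
    epoch_band_power,
    modified_periodogram,
    segment,
    welch_psd,
)
from drivevitals.synth import EegStateSpec, gen_eeg
from drivevitals.trace import SignalTrace


def welch_transcription(x, m, d, w, fs):
    """Independent oracle: the Welch estimate written as literal sums.

    Segments x_i[n] = x[n + iD]; modified periodogram
    |sum_n x_i[n] w[n] e^{-j2 pi n f}|^2 / (M U fs) with U = (1/M) sum w^2;
    the estimate is the arithmetic mean over segments, one-sided.
    """
    n_sig = len(x)
    k = (n_sig - m) // d + 1
    u = sum(w[n] ** 2 for n in range(m)) / m
    nf = m // 2 + 1
    p = np.zeros(nf)
    for i in range(k):
        for fi in range(nf):
            acc = 0.0 + 0.0j
            for n in range(m):
                acc += x[i * d + n] * w[n] * np.exp(-2j * np.pi * n * fi / m)
            p[fi] += abs(acc) ** 2 / (m * u * fs)
    p /= k
    if m % 2 == 0:
        p[1:-1] *= 2.0
    else:
        p[1:] *= 2.0
    return p


class TestSegment:
    def test_no_overlap_when_hop_equals_length(self):
        segs = segment(np.arange(8.0), 4, 4)
        assert segs.shape == (2, 4)
        assert np.array_equal(segs[0], [0, 1, 2, 3])
        assert np.array_equal(segs[1], [4, 5, 6, 7])

    def test_half_overlap(self):
        segs = segment(np.arange(8.0), 4, 2)
        assert segs.shape == (3, 4)
        assert np.array_equal(segs[1], [2, 3, 4, 5])

    def test_single_segment_equals_signal(self):
        x = np.arange(4.0)
        segs = segment(x, 4, 1)
        assert segs.shape == (1, 4) and np.array_equal(segs[0], x)

    def test_segment_count_formula_exhaustive(self):
        """K = floor((N-M)/D) + 1 against brute-force index enumeration
        for every (N <= 32, M <= N, D <= M)."""
        for n in range(1, 33):
            x = np.arange(float(n))
            for m in range(1, n + 1):
                for d in range(1, m + 1):
                    segs = segment(x, m, d)
                    brute = [
                        x[i * d : i * d + m]
                        for i in range(n)
                        if i * d + m <= n
                    ]
                    assert segs.shape[0] == (n - m) // d + 1 == len(brute)
                    assert np.array_equal(segs, np.array(brute))

    def test_segment_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            segment(np.arange(4.0), 5, 1)


class TestModifiedPeriodogram:
    def test_rectangular_window_is_plain_periodogram(self, rng):
        x = rng.normal(size=32)
        est = modified_periodogram(x, np.ones(32), fs=32.0)
        plain = np.abs(np.fft.rfft(x)) ** 2 / (32 * 32.0)
        plain[1:-1] *= 2
        assert np.allclose(est.power, plain, atol=1e-12)

    @pytest.mark.parametrize("window", ["rectangular", "hann"])
    def test_unit_sinusoid_integrates_to_half(self, window):
        fs, m = 64.0, 256
        t = np.arange(m) / fs
        x = np.sin(2 * np.pi * 8.0 * t)  # bin-centered
        w = WelchSpec(m, m, window=window, fs=fs).taper()
        est = modified_periodogram(x, w, fs)
        assert est.freqs[np.argmax(est.power)] == pytest.approx(8.0)
        assert est.total_power == pytest.approx(0.5, rel=0.01)

    def test_matches_direct_sum_on_random_segment(self, rng):
        x = rng.normal(size=16)
        w = WelchSpec(16, 16, fs=8.0).taper()
        est = modified_periodogram(x, w, 8.0)
        oracle = welch_transcription(x, 16, 16, w, 8.0)
        assert np.allclose(est.power, oracle, atol=1e-10)

    def test_zero_energy_window_rejected(self):
        with pytest.raises(ValueError):
            modified_periodogram(np.ones(8), np.zeros(8), 8.0)


class TestWelch:
    def test_matches_transcription_oracle(self, rng):
        for n, m, d in ((64, 16, 8), (48, 12, 6), (33, 8, 3)):
            x = rng.normal(size=n)
            spec = WelchSpec(m, d, fs=10.0)
            mine = welch_psd(x, spec).power
            oracle = welch_transcription(x, m, d, spec.taper(), 10.0)
            rel = np.max(np.abs(mine - oracle)) / np.max(oracle)
            assert rel < 1e-10

    def test_white_noise_integrates_to_variance(self, rng):
        x = rng.normal(0, 2.0, 16384)
        psd = welch_psd(x, WelchSpec(512, 256, fs=100.0))
        assert psd.total_power == pytest.approx(float(np.var(x)), rel=0.1)

    def test_overlap_choice_consistent_on_stationary_tone(self):
        fs = 100.0
        t = np.arange(4096) / fs
        x = np.sin(2 * np.pi * 12.5 * t)
        full = welch_psd(x, WelchSpec(256, 256, fs=fs))
        half = welch_psd(x, WelchSpec(256, 128, fs=fs))
        assert band_power(full, 10, 15) == pytest.approx(
            band_power(half, 10, 15), rel=0.05
        )

    def test_constant_signal_power_at_dc(self):
        psd = welch_psd(
            np.full(256, 3.0), WelchSpec(64, 32, window="rectangular", fs=10.0)
        )
        assert np.argmax(psd.power) == 0
        assert np.all(psd.power[1:] < 1e-20 * psd.power[0] + 1e-20)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 5))
    def test_scale_equivariance(self, scale, seed):
        x = np.random.default_rng(seed).normal(size=128)
        spec = WelchSpec(32, 16, fs=10.0)
        assert np.allclose(
            welch_psd(scale * x, spec).power,
            scale**2 * welch_psd(x, spec).power,
            rtol=1e-9,
        )


class TestBandPower:
    def test_tone_power_concentrates_in_band(self):
        fs = 100.0
        t = np.arange(8192) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        psd = welch_psd(x, WelchSpec(1024, 512, fs=fs))
        assert band_power(psd, 8, 12) >= 0.9 * psd.total_power

    def test_disjoint_bands_sum_to_total(self, rng):
        psd = welch_psd(rng.normal(size=512), WelchSpec(128, 64, fs=100.0))
        parts = band_power(psd, 0, 13.3) + band_power(psd, 13.3, 31.0) + band_power(
            psd, 31.0, 50.0
        )
        assert parts == pytest.approx(psd.total_power, rel=1e-9)

    def test_band_outside_support_is_zero(self):
        fs = 100.0
        t = np.arange(4096) / fs
        psd = welch_psd(np.sin(2 * np.pi * 5 * t), WelchSpec(512, 256, fs=fs))
        assert band_power(psd, 40, 49) < 1e-6 * psd.total_power

    def test_inverted_band_rejected(self):
        psd = welch_psd(np.ones(64), WelchSpec(32, 16, fs=10.0))
        with pytest.raises(ValueError):
            band_power(psd, 12, 8)


@pytest.fixture(scope="module")
def baseline():
    epoch = gen_eeg(EegStateSpec.for_state("eyes_open"), 8.0, 500.0, seed=21)
    return epoch_band_power(epoch)


class TestDrowsiness:
    def test_drowsy_epoch_flags_against_eyes_open_baseline(self, baseline):
        epoch = gen_eeg(EegStateSpec.for_state("drowsy"), 8.0, 500.0, seed=22)
        assert drowsiness_score(epoch, baseline, threshold_mult=1.5).drowsy

    def test_epoch_identical_to_baseline_not_drowsy(self):
        epoch = gen_eeg(EegStateSpec.for_state("eyes_open"), 8.0, 500.0, seed=23)
        bp = epoch_band_power(epoch)
        for mult in (1.01, 1.5, 3.0):
            assert not drowsiness_score(epoch, bp, threshold_mult=mult).drowsy

    def test_score_monotone_in_alpha_amplitude(self, baseline):
        ratios = []
        for alpha in (10.0, 25.0, 60.0, 120.0):
            epoch = gen_eeg(EegStateSpec("sweep", alpha, 15.0, 5.0), 8.0, 500.0, seed=9)
            ratios.append(drowsiness_score(epoch, baseline).ratio)
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_zero_beta_power_flagged_not_raised(self):
        t = np.arange(4000) / 500.0
        epoch = SignalTrace(40 * np.sin(2 * np.pi * 10 * t), 500.0)
        bp = BandPower(alpha_power=1.0, beta_power=0.0)
        score = drowsiness_score(epoch, bp)
        assert score.indeterminate and not score.drowsy
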