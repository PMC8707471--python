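"""Filtering and wavelet machinery against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drivevitals.conditioning import (
    FilterSpec,
    WaveletSpec,
    apply_filter,
    dwt_coeffs,
    swt_denoise,
)
from drivevitals.synth import EcgProfile, gen_ecg
from drivevitals.trace import SignalTrace


def _tone(freq, fs=500.0, duration=4.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalTrace(np.sin(2 * np.pi * freq * t), fs)


def _rms(x):
    return float(np.sqrt(np.mean(x**2)))


class TestFilters:
    def test_notch_kills_mains_tone(self):
        tone = _tone(50.0, duration=10.0)
        out = apply_filter(tone, FilterSpec("notch", f0=50.0))
        mid = slice(len(tone) // 4, -len(tone) // 4)  # steady state
        assert _rms(out.samples[mid]) < 0.01 * _rms(tone.samples[mid])

    def test_bandpass_passband_is_flat(self):
        tone = _tone(10.0)
        out = apply_filter(tone, FilterSpec("bandpass", f_lo=0.5, f_hi=35.0))
        mid = slice(len(tone) // 4, -len(tone) // 4)  # avoid edge transients
        assert _rms(out.samples[mid]) == pytest.approx(_rms(tone.samples[mid]), rel=0.05)

    def test_zero_input_zero_output(self):
        zero = SignalTrace(np.zeros(1000), 500.0)
        for spec in (
            FilterSpec("notch", f0=50.0),
            FilterSpec("bandpass", f_lo=1.0, f_hi=40.0),
            FilterSpec("moving_average", window_len=5),
        ):
            assert np.all(apply_filter(zero, spec).samples == 0)

    def test_zero_phase_no_group_delay(self):
        tone = _tone(10.0)
        out = apply_filter(tone, FilterSpec("bandpass", f_lo=5.0, f_hi=20.0))
        xc = np.correlate(out.samples, tone.samples, mode="full")
        lag = int(np.argmax(xc)) - (len(tone) - 1)
        assert lag == 0

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            apply_filter(_tone(10.0), FilterSpec("notch", f0=300.0))

    def test_length_preserved(self):
        tone = _tone(7.0)
        for spec in (
            FilterSpec("lowpass", f0=30.0),
            FilterSpec("moving_average", window_len=9),
        ):
            assert len(apply_filter(tone, spec)) == len(tone)


def _haar_basis(n, levels):
    """Brute-force orthonormal Haar basis for length n = 2^k signals.

    Row layout matches [cA_J, cD_J, ..., cD_1]: scaling vectors first, then
    wavelet vectors coarsest to finest. Wavelet vectors are +1 on the first
    half of their support, -1 on the second, normalised to unit energy.
    """
    rows = []
    width = 2**levels
    for start in range(0, n, width):  # scaling functions at depth `levels`
        v = np.zeros(n)
        v[start : start + width] = 1.0 / np.sqrt(width)
        rows.append(v)
    for j in range(levels, 0, -1):  # detail coefficients, coarsest first
        w = 2**j
        for start in range(0, n, w):
            v = np.zeros(n)
            v[start : start + w // 2] = 1.0
            v[start + w // 2 : start + w] = -1.0
            rows.append(v / np.sqrt(w))
    return np.stack(rows)


class TestDwt:
    def test_constant_signal_has_no_detail(self):
        trace = SignalTrace(np.ones(4), 100.0)
        coeffs = dwt_coeffs(trace, WaveletSpec(levels=1))
        assert np.allclose(coeffs[-1], 0.0)

    def test_coefficients_equal_basis_inner_products(self, rng):
        x = rng.normal(size=8)
        basis = _haar_basis(8, 3)
        expected = basis @ x
        coeffs = dwt_coeffs(SignalTrace(x, 100.0), WaveletSpec(levels=3))
        flat = np.concatenate(coeffs)
        assert np.allclose(flat, expected, atol=1e-10)

    def test_haar_basis_is_orthonormal(self):
        basis = _haar_basis(16, 2)
        assert np.allclose(basis @ basis.T, np.eye(len(basis)), atol=1e-12)

    def test_parseval_energy_preserved(self, rng):
        x = rng.normal(size=64)
        coeffs = dwt_coeffs(SignalTrace(x, 100.0), WaveletSpec(levels=3))
        energy = sum(float(np.sum(c**2)) for c in coeffs)
        assert energy == pytest.approx(float(np.sum(x**2)), rel=1e-12)

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            dwt_coeffs(SignalTrace(np.arange(4.0), 100.0), WaveletSpec(levels=5))


class TestSwtDenoise:
    def test_zero_threshold_is_identity(self, clean_ecg_75):
        spec = WaveletSpec(threshold_rule="fixed", threshold_values=(0.0, 0.0, 0.0))
        out = swt_denoise(clean_ecg_75, spec)
        assert np.allclose(out.samples, clean_ecg_75.samples, atol=1e-8)

    def test_denoising_reduces_rmse_at_5db(self, rng):
        clean = gen_ecg(EcgProfile.for_class("normal", 75.0), 10.0, 500.0, seed=1)
        sig_power = float(np.mean(clean.samples**2))
        noise_sd = np.sqrt(sig_power / 10 ** (5 / 10))  # SNR 5 dB
        noisy = clean.with_samples(
            clean.samples + rng.normal(0, noise_sd, len(clean))
        )
        den = swt_denoise(noisy, WaveletSpec())
        rmse_noisy = np.sqrt(np.mean((noisy.samples - clean.samples) ** 2))
        rmse_den = np.sqrt(np.mean((den.samples - clean.samples) ** 2))
        assert rmse_den < rmse_noisy

    def test_huge_threshold_leaves_only_approximation(self, rng):
        x = rng.normal(size=256)
        spec = WaveletSpec(threshold_rule="fixed", threshold_values=(1e9,) * 3)
        out = swt_denoise(SignalTrace(x, 100.0), spec)
        # all detail killed: only the smooth level-3 approximation remains
        assert np.std(out.samples) < np.std(x)
        assert np.max(np.abs(np.diff(out.samples))) < np.max(np.abs(np.diff(x)))

    def test_output_length_equals_input_length(self, rng):
        for n in (100, 255, 256):
            out = swt_denoise(SignalTrace(rng.normal(size=n), 100.0))
            assert len(out) == n

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(shift=st.integers(min_value=0, max_value=63), seed=st.integers(0, 10))
    def test_shift_equivariance(self, shift, seed):
        x = np.random.default_rng(seed).normal(size=64)
        spec = WaveletSpec(threshold_rule="fixed", threshold_values=(0.3, 0.3, 0.3))
        direct = swt_denoise(SignalTrace(np.roll(x, shift), 100.0), spec).samples
        shifted = np.roll(swt_denoise(SignalTrace(x, 100.0), spec).samples, shift)
        assert np.allclose(direct, shifted, atol=1e-10)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            WaveletSpec(family="nonexistent7")
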