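"""Generators: label/signal consistency, determinism, channel physics."""

import numpy as np
import pytest
from scipy.signal import butter, find_peaks, sosfiltfilt, welch

from drivevitals.synth import (
    DEFAULT_CHANNEL,
    EEG_STATE_DOMINANCE,
    EEG_STATE_PRESETS,
    CapacitiveChannel,
    EcgProfile,
    EegStateSpec,
    apply_capacitive_channel,
    gen_ecg,
    gen_eeg,
    gen_ppg_pair,
    gen_thermal_sequence,
)
from drivevitals.oximetry import estimate_spo2, extract_ac_dc, ratio_R


def _bandlimited_variance(x, fs, lo, hi):
    """Independent band-power oracle: band-pass then variance."""
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return float(np.var(sosfiltfilt(sos, x)))


class TestEcg:
    def test_zero_duration_gives_empty_trace(self):
        trace = gen_ecg(EcgProfile.for_class("normal"), 0.0, 500.0, seed=0)
        assert len(trace) == 0

    def test_r_peak_count_matches_rate(self):
        # independent local-maxima oracle, not the package's detector
        trace = gen_ecg(EcgProfile.for_class("normal", 60.0), 10.0, 500.0, seed=3)
        peaks, _ = find_peaks(
            trace.samples, height=0.6 * trace.samples.max(), distance=int(0.4 * 500)
        )
        assert abs(len(peaks) - 10) <= 1

    def test_blood_pressure_classes_are_distinct(self):
        beats = {}
        for label in ("normal", "hypotension", "hypertension"):
            t = gen_ecg(
                EcgProfile.for_class(label, 60.0), 2.0, 500.0, seed=0
            ).samples
            beats[label] = t / np.linalg.norm(t)
        labels = list(beats)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                xc = np.correlate(beats[a], beats[b], mode="full")
                assert np.max(np.abs(xc)) < 0.999

    def test_determinism(self):
        p = EcgProfile.for_class("hypertension", 80.0)
        a = gen_ecg(p, 5.0, 500.0, seed=42).samples
        b = gen_ecg(p, 5.0, 500.0, seed=42).samples
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("fs", [0.0, -100.0, 100.0])
    def test_invalid_fs_rejected(self, fs):
        with pytest.raises(ValueError):
            gen_ecg(EcgProfile.for_class("normal"), 1.0, fs, seed=0)

    def test_r_must_dominate_p(self):
        with pytest.raises(ValueError):
            EcgProfile("weird", {"P": (-0.2, 1.0, 0.02), "R": (0.0, 0.5, 0.01)})


class TestEeg:
    @pytest.mark.parametrize("state", sorted(EEG_STATE_PRESETS))
    def test_band_dominance_matches_state(self, state):
        """Alpha power exceeds beta power exactly in the alpha-dominant
        states (relaxation/drowsiness with eyes closed), per the direct
        band-limited-variance oracle."""
        trace = gen_eeg(EegStateSpec.for_state(state), 10.0, 500.0, seed=5)
        alpha = _bandlimited_variance(trace.samples, 500.0, 8, 12)
        beta = _bandlimited_variance(trace.samples, 500.0, 14, 25)
        expected_alpha_dominant = EEG_STATE_DOMINANCE[state] == "alpha"
        assert (alpha > beta) == expected_alpha_dominant

    def test_zero_amplitudes_give_zero_trace(self):
        spec = EegStateSpec("quiet", 0.0, 0.0, 0.0)
        trace = gen_eeg(spec, 2.0, 250.0, seed=0)
        assert np.all(trace.samples == 0)

    def test_alpha_component_respects_physiological_bound(self):
        trace = gen_eeg(
            EegStateSpec("eyes_closed_relaxed", 40.0, 10.0, 0.0), 10.0, 500.0, seed=1
        )
        sos = butter(4, [8, 12], btype="bandpass", fs=500.0, output="sos")
        assert np.max(np.abs(sosfiltfilt(sos, trace.samples))) <= 150.0

    @pytest.mark.parametrize("bad_alpha", [2.0, 151.0, -5.0])
    def test_alpha_amplitude_out_of_range_rejected(self, bad_alpha):
        with pytest.raises(ValueError):
            EegStateSpec("custom", bad_alpha, 10.0)


class TestPpg:
    def test_round_trip_recovers_truth(self):
        pair = gen_ppg_pair(98.0, 75.0, 10.0, 500.0, seed=2)
        assert abs(estimate_spo2(pair).spo2_pct - 98.0) <= 1.0

    def test_zero_ac_is_flagged_indeterminate(self):
        pair = gen_ppg_pair(95.0, 75.0, 10.0, 500.0, seed=0)
        flat = pair.red.with_samples(np.full(len(pair.red), 1.0))
        from drivevitals.synth import PpgPair

        est = estimate_spo2(PpgPair(flat, pair.ir))
        assert est.indeterminate and np.isnan(est.spo2_pct)

    def test_lower_saturation_gives_larger_ratio(self):
        r = {}
        for s in (85.0, 98.0):
            pair = gen_ppg_pair(s, 75.0, 10.0, 500.0, seed=1)
            r[s] = ratio_R(extract_ac_dc(pair))
        assert r[85.0] > r[98.0]

    def test_out_of_domain_saturation_rejected(self):
        with pytest.raises(ValueError):
            gen_ppg_pair(55.0, 75.0, 5.0, 500.0, seed=0)


class TestThermal:
    def test_ambient_gradient_near_zero(self):
        frames = gen_thermal_sequence("ambient", 60, 1.0, seed=6)
        from drivevitals.thermal import temporal_gradient

        assert np.max(np.abs(temporal_gradient(frames))) < 0.02

    def test_flame_regime_exceeds_flame_threshold(self):
        frames = gen_thermal_sequence("flame", 10, 10.0, seed=6)
        assert max(f.temps.max() for f in frames) >= 60.0

    def test_every_frame_has_64_points(self):
        for f in gen_thermal_sequence("warming", 5, 1.0, seed=0):
            assert f.temps.size == 64

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            gen_thermal_sequence("volcano", 5, 1.0, seed=0)


class TestCapacitiveChannel:
    def test_identity_channel(self, clean_ecg_75):
        out = apply_capacitive_channel(clean_ecg_75, CapacitiveChannel())
        assert np.allclose(out.samples, clean_ecg_75.samples, atol=1e-12)

    def test_single_layer_divider_matches_hand_computation(self):
        ch = CapacitiveChannel(layers=((0.0, 10e-9),), z_input=1e8)
        f = 10.0
        zc = 1.0 / (1j * 2 * np.pi * f * 10e-9)
        expected = abs(1e8 / (1e8 + zc))
        got = abs(ch.transfer(np.array([f]))[0])
        assert got == pytest.approx(expected, rel=1e-6)

    def test_mains_hum_appears_at_50_hz(self, clean_ecg_75):
        ch = CapacitiveChannel(mains_amp=0.5, seed=3)
        out = apply_capacitive_channel(clean_ecg_75, ch)
        f, p = welch(out.samples, fs=clean_ecg_75.fs, nperseg=4096)
        band = (f > 40) & (f < 60)
        assert f[band][np.argmax(p[band])] == pytest.approx(50.0, abs=0.5)

    def test_deterministic_given_seed(self, clean_ecg_75):
        a = apply_capacitive_channel(clean_ecg_75, DEFAULT_CHANNEL).samples
        b = apply_capacitive_channel(clean_ecg_75, DEFAULT_CHANNEL).samples
        assert np.array_equal(a, b)

    def test_linearity_without_noise(self, clean_ecg_75):
        ch = CapacitiveChannel(layers=((0.0, 100e-12), (1e-3, 220e-12)))
        x, y = clean_ecg_75, clean_ecg_75.with_samples(clean_ecg_75.samples[::-1])
        lhs = apply_capacitive_channel(
            x.with_samples(2.0 * x.samples + 3.0 * y.samples), ch
        ).samples
        rhs = (
            2.0 * apply_capacitive_channel(x, ch).samples
            + 3.0 * apply_capacitive_channel(y, ch).samples
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_invalid_layer_rejected(self):
        with pytest.raises(ValueError):
            CapacitiveChannel(layers=((0.0, 0.0),))
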