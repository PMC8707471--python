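"""Ground-truth-labelled synthetic physiological signals.

The recordings behind a non-contact in-cabin monitoring system (capacitive
EEG/ECG electrodes in the seat, a steering-wheel pulse oximeter, a thermopile
grid) are not publicly available, so every downstream stage in this package
is exercised against synthetic signals whose ground truth is known by
construction:

* ECG — a periodic sum of Gaussian bumps per beat (P, Q, R, S, T), with
  template parameter sets for three blood-pressure classes.
* EEG — narrow-band alpha (8-12 Hz) and beta (14-25 Hz) oscillations plus
  broadband noise, with state presets that encode the documented ordering
  (alpha dominates when eyes close / drowsiness sets in, beta when alert).
* PPG — a red/infrared pair whose AC/DC modulation depths are chosen by
  *inverting* the oximetry module's own ratio-of-ratios formula and
  calibration table, so the configured SpO2 is recovered by construction.
* Thermal — 8x8 frame sequences in ambient / warming / flame regimes.

`apply_capacitive_channel` degrades a trace through the coupling network a
through-clothing electrode sees: each insulating layer contributes a series
LC impedance Z_i = jwL_i + 1/(jwC_i), summing to Z_tot; the electrode input
impedance forms a voltage divider against Z_tot; vehicle electrics add 50 Hz
hum and impulsive spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .oximetry import CalibrationTable, default_calibration_table
from .thermal import GRID_SHAPE, ThermalFrame
from .trace import DEFAULT_FS, SignalTrace

__all__ = [
    "EcgProfile",
    "EegStateSpec",
    "CapacitiveChannel",
    "PpgPair",
    "gen_ecg",
    "gen_eeg",
    "gen_ppg_pair",
    "gen_thermal_sequence",
    "apply_capacitive_channel",
    "ECG_CLASS_TEMPLATES",
    "EEG_STATE_PRESETS",
]


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

#: Per-class wave templates: name -> (offset from R peak [s], amplitude [mV],
#: Gaussian width [s]). The three classes are qualitative morphology presets
#: (normal sinus, hypotension-like low-voltage, hypertension-like high
#: R/strain), with no claim of clinical fidelity.
ECG_CLASS_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "normal": {
        "P": (-0.20, 0.15, 0.025),
        "Q": (-0.030, -0.10, 0.010),
        "R": (0.0, 1.00, 0.012),
        "S": (0.030, -0.25, 0.010),
        "T": (0.25, 0.35, 0.045),
    },
    "hypotension": {
        "P": (-0.20, 0.08, 0.030),
        "Q": (-0.030, -0.05, 0.010),
        "R": (0.0, 0.55, 0.014),
        "S": (0.030, -0.12, 0.012),
        "T": (0.28, 0.15, 0.055),
    },
    "hypertension": {
        "P": (-0.20, 0.20, 0.022),
        "Q": (-0.030, -0.18, 0.010),
        "R": (0.0, 1.45, 0.011),
        "S": (0.030, -0.45, 0.010),
        "T": (0.24, 0.25, 0.040),  # flattened-T / strain pattern
    },
}


@dataclass(frozen=True)
class EcgProfile:
    """Beat morphology template plus target heart rate.

    ``waves`` maps wave names to (offset_s, amplitude_mV, width_s) Gaussian
    bump parameters, offsets relative to the R peak.
    """

    class_label: str
    waves: dict[str, tuple[float, float, float]]
    hr_bpm: float = 70.0
    jitter_sd_s: float = 0.01  # beat-to-beat timing jitter

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if "R" not in self.waves:
            raise ValueError("template must contain an R wave")
        if "P" in self.waves and self.waves["R"][1] <= self.waves["P"][1]:
            raise ValueError("R amplitude must exceed P amplitude")

    @classmethod
    def for_class(cls, class_label: str, hr_bpm: float = 70.0, **kw) -> "EcgProfile":
        if class_label not in ECG_CLASS_TEMPLATES:
            raise ValueError(
                f"unknown ECG class {class_label!r}; "
                f"expected one of {sorted(ECG_CLASS_TEMPLATES)}"
            )
        return cls(class_label, dict(ECG_CLASS_TEMPLATES[class_label]), hr_bpm, **kw)


def gen_ecg(
    profile: EcgProfile,
    duration_s: float,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> SignalTrace:
    """Synthesise a P-QRS-T ECG trace at ``profile.hr_bpm``.

    Each beat is a sum of Gaussian bumps; beat onsets carry small seeded
    timing jitter. Requires fs >= 250 Hz so the QRS complex is resolved.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if fs < 250:
        raise ValueError("ECG synthesis requires fs >= 250 Hz")
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    if n:
        rng = np.random.default_rng(seed)
        period = 60.0 / profile.hr_bpm
        # R-peak times: regular grid + jitter; first beat away from the edge
        # so its P wave is not clipped.
        n_beats = int(math.ceil(duration_s / period)) + 1
        r_times = 0.35 + period * np.arange(n_beats)
        r_times = r_times + rng.normal(0.0, profile.jitter_sd_s, n_beats)
        for r_t in r_times:
            if r_t < -0.5 or r_t > duration_s + 0.5:
                continue
            for offset, amp, width in profile.waves.values():
                x += amp * np.exp(-0.5 * ((t - r_t - offset) / width) ** 2)
    return SignalTrace(x, fs, channel=f"ecg_{profile.class_label}", units="mV")


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (14.0, 25.0)
ALPHA_AMP_RANGE_UV = (5.0, 150.0)  # physiological alpha amplitude bound

#: State presets (alpha_amp, beta_amp, broadband_noise_amp) in uV. States in
#: which alpha dominates (relaxation/drowsiness, eyes closed) versus states in
#: which beta dominates (alert, stimulated) follow the standard occipital EEG
#: picture; typical waking alpha sits between 20 and 50 uV.
EEG_STATE_PRESETS: dict[str, tuple[float, float, float]] = {
    "eyes_open": (10.0, 20.0, 5.0),
    "eyes_closed_relaxed": (40.0, 10.0, 5.0),
    "drowsy": (60.0, 8.0, 5.0),
    "stress": (8.0, 35.0, 5.0),
    "emotion": (25.0, 18.0, 5.0),
    "distraction": (12.0, 15.0, 25.0),
}

#: Which band carries more power in each state (alpha variance A^2/2 vs beta).
EEG_STATE_DOMINANCE: dict[str, str] = {
    "eyes_open": "beta",
    "eyes_closed_relaxed": "alpha",
    "drowsy": "alpha",
    "stress": "beta",
    "emotion": "alpha",
    "distraction": "beta",
}


@dataclass(frozen=True)
class EegStateSpec:
    """Amplitude recipe for one cognitive/vigilance state."""

    state: str
    alpha_amp: float  # uV, peak amplitude of the 8-12 Hz component
    beta_amp: float  # uV, peak amplitude of the 14-25 Hz component
    broadband_noise_amp: float = 5.0  # uV, white-noise standard deviation

    def __post_init__(self) -> None:
        lo, hi = ALPHA_AMP_RANGE_UV
        if self.alpha_amp != 0 and not lo <= self.alpha_amp <= hi:
            raise ValueError(
                f"alpha amplitude {self.alpha_amp} uV outside physiological "
                f"range [{lo}, {hi}] uV"
            )
        if self.beta_amp < 0 or self.broadband_noise_amp < 0:
            raise ValueError("amplitudes must be non-negative")

    @classmethod
    def for_state(cls, state: str) -> "EegStateSpec":
        if state not in EEG_STATE_PRESETS:
            raise ValueError(
                f"unknown EEG state {state!r}; expected one of {sorted(EEG_STATE_PRESETS)}"
            )
        a, b, n = EEG_STATE_PRESETS[state]
        return cls(state, a, b, n)


def gen_eeg(
    spec: EegStateSpec,
    duration_s: float,
    fs: float = DEFAULT_FS,
    seed: int = 0,
) -> SignalTrace:
    """Synthesise one EEG epoch: alpha + beta sinusoids + white noise.

    The alpha component is a pure tone at a seeded frequency inside 8-12 Hz
    with a random phase, so its peak amplitude is exactly ``alpha_amp`` and
    never exceeds the physiological bound. Likewise for beta inside 14-25 Hz.
    """
    if fs < 100:
        raise ValueError("EEG synthesis requires fs >= 100 Hz")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    f_alpha = rng.uniform(ALPHA_BAND[0] + 0.5, ALPHA_BAND[1] - 0.5)
    f_beta = rng.uniform(BETA_BAND[0] + 1.0, BETA_BAND[1] - 1.0)
    ph_a, ph_b = rng.uniform(0, 2 * np.pi, 2)
    x = spec.alpha_amp * np.sin(2 * np.pi * f_alpha * t + ph_a)
    x = x + spec.beta_amp * np.sin(2 * np.pi * f_beta * t + ph_b)
    if spec.broadband_noise_amp > 0:
        x = x + rng.normal(0.0, spec.broadband_noise_amp, n)
    return SignalTrace(x, fs, channel=f"eeg_{spec.state}", units="uV")


# ---------------------------------------------------------------------------
# PPG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PpgPair:
    """Red (660 nm) and infrared (910 nm) PPG traces with ground truth."""

    red: SignalTrace
    ir: SignalTrace
    spo2_true: float | None = None

    def __post_init__(self) -> None:
        if self.red.fs != self.ir.fs or len(self.red) != len(self.ir):
            raise ValueError("red and IR traces must share fs and length")
        if self.spo2_true is not None and not 0 < self.spo2_true <= 100:
            raise ValueError("spo2_true must lie in (0, 100]")


def gen_ppg_pair(
    spo2_true: float,
    hr_bpm: float = 75.0,
    duration_s: float = 10.0,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    table: CalibrationTable | None = None,
    perfusion_ir: float = 0.04,
    noise_amp: float = 0.0,
) -> PpgPair:
    """Dual-wavelength PPG whose modulation depths encode ``spo2_true``.

    The IR channel gets a fixed perfusion (peak-to-trough AC over DC) of
    ``perfusion_ir``; the red channel's modulation is solved from the
    log-ratio formula, m_red = m_ir ** R(spo2_true), with R taken from the
    *inverse* of the configured calibration table. Running the oximetry
    pipeline on the result therefore recovers ``spo2_true`` by construction.
    """
    if table is None:
        table = default_calibration_table()
    if not 70 <= spo2_true <= 100:
        raise ValueError("spo2_true must lie in [70, 100] %")
    r_value = table.r_for_spo2(spo2_true)
    m_ir = perfusion_ir
    m_red = m_ir**r_value
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    pulse = 0.5 * np.sin(2 * np.pi * hr_bpm / 60.0 * t + phase)  # ptp = 1
    dc_red, dc_ir = 1.0, 1.2
    red = dc_red * (1.0 + m_red * pulse)
    ir = dc_ir * (1.0 + m_ir * pulse)
    if noise_amp > 0:
        red = red + rng.normal(0, noise_amp, n)
        ir = ir + rng.normal(0, noise_amp, n)
    return PpgPair(
        SignalTrace(red, fs, channel="ppg_red_660nm", units="a.u."),
        SignalTrace(ir, fs, channel="ppg_ir_910nm", units="a.u."),
        spo2_true=spo2_true,
    )


# ---------------------------------------------------------------------------
# Thermal frames
# ---------------------------------------------------------------------------

THERMAL_REGIMES = ("ambient", "warming", "flame")


def gen_thermal_sequence(
    regime: str,
    n_frames: int = 20,
    fps: float = 10.0,
    seed: int = 0,
    ambient_c: float = 22.0,
    noise_sd_c: float = 0.1,
    warming_rate_c_s: float = 0.08,
    flame_temp_c: float = 180.0,
) -> list[ThermalFrame]:
    """Generate an 8x8 frame sequence in one of three regimes.

    ambient: constant baseline + per-pixel Gaussian noise.
    warming: slow linear ramp on a central 2x2 sub-region (cabin heat-up).
    flame:   two localized hot pixels flickering around ``flame_temp_c`` with
             large frame-to-frame transitions.
    """
    if regime not in THERMAL_REGIMES:
        raise ValueError(
            f"unknown thermal regime {regime!r}; expected one of {THERMAL_REGIMES}"
        )
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    frames: list[ThermalFrame] = []
    flame_pixels = [(2, 5), (3, 5)]
    for k in range(n_frames):
        t = k / fps
        grid = ambient_c + rng.normal(0.0, noise_sd_c, GRID_SHAPE)
        if regime == "warming":
            grid[3:5, 3:5] += warming_rate_c_s * t
        elif regime == "flame" and k >= 1:  # ignition after the first frame
            for r, c in flame_pixels:
                grid[r, c] = flame_temp_c * rng.uniform(0.6, 1.0)
        frames.append(ThermalFrame(grid, time_s=t))
    return frames


# ---------------------------------------------------------------------------
# Capacitive coupling channel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CapacitiveChannel:
    """Through-clothing coupling network plus vehicle electrical noise.

    Each insulating layer between body and electrode plate (clothing, air,
    seat textile) contributes a series impedance Z_i = jwL_i + 1/(jwC_i);
    the layers sum to Z_tot, which forms a voltage divider against the
    amplifier input impedance ``z_input``:  H(w) = Z_in / (Z_in + Z_tot).
    On top of the linear attenuation, mains hum (50 Hz) and Poisson-timed
    biphasic voltage spikes (ignition/inductive transients) are added.
    A channel with no layers and zero noise amplitudes is the identity.
    """

    layers: tuple[tuple[float, float], ...] = ()  # (L_i [H], C_i [F])
    z_input: float = 1e8  # amplifier input impedance [ohm]
    mains_amp: float = 0.0  # hum amplitude, signal units
    mains_freq: float = 50.0  # Hz
    spike_rate: float = 0.0  # impulses per second
    spike_amp: float = 0.0  # impulse amplitude, signal units
    seed: int = 0

    def __post_init__(self) -> None:
        for L, C in self.layers:
            if C <= 0:
                raise ValueError("layer capacitance must be positive")
            if L < 0:
                raise ValueError("layer inductance must be non-negative")
        if self.z_input <= 0:
            raise ValueError("input impedance must be positive")

    def total_impedance(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Z_tot(w) = sum_i (jwL_i + 1/(jwC_i)), infinite at DC."""
        w = 2 * np.pi * np.asarray(freqs_hz, dtype=float)
        z = np.zeros_like(w, dtype=complex)
        with np.errstate(divide="ignore"):
            for L, C in self.layers:
                z = z + 1j * w * L + 1.0 / (1j * w * C)
        return z

    def transfer(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Voltage-divider transfer H = Z_in / (Z_in + Z_tot); H(0) = 0
        when any capacitive layer is present (a capacitor blocks DC)."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        if not self.layers:
            return np.ones_like(freqs_hz, dtype=complex)
        h = np.empty_like(freqs_hz, dtype=complex)
        nz = freqs_hz != 0
        h[nz] = self.z_input / (self.z_input + self.total_impedance(freqs_hz[nz]))
        h[~nz] = 0.0
        return h


#: Default channel: two clothing/seat layers with typical through-fabric
#: coupling capacitances (order 100 pF), a 100 Mohm front-end, moderate mains
#: hum and occasional ignition spikes. Amplitudes are in the signal's own
#: units, sized for a millivolt-scale ECG.
DEFAULT_CHANNEL = CapacitiveChannel(
    layers=((0.0, 100e-12), (0.0, 220e-12)),
    z_input=1e8,
    mains_amp=0.1,
    spike_rate=0.5,
    spike_amp=0.5,
    seed=0,
)


def apply_capacitive_channel(
    trace: SignalTrace, channel: CapacitiveChannel
) -> SignalTrace:
    """Degrade a trace through the coupling network and vehicle noise.

    Linear attenuation is applied in the frequency domain (real FFT multiplied
    by the divider transfer function); mains hum and seeded biphasic spikes
    are then added in the time domain. Deterministic given ``channel.seed``.
    """
    if len(trace) == 0:
        raise ValueError("cannot apply channel to an empty trace")
    freqs = np.fft.rfftfreq(len(trace), d=1.0 / trace.fs)
    spec = np.fft.rfft(trace.samples) * channel.transfer(freqs)
    y = np.fft.irfft(spec, n=len(trace))
    rng = np.random.default_rng(channel.seed)
    if channel.mains_amp > 0:
        y = y + channel.mains_amp * np.sin(
            2 * np.pi * channel.mains_freq * trace.times
        )
    if channel.spike_rate > 0 and channel.spike_amp > 0:
        n_spikes = rng.poisson(channel.spike_rate * trace.duration_s)
        if n_spikes:
            idx = rng.integers(0, max(1, len(trace) - 1), n_spikes)
            signs = rng.choice((-1.0, 1.0), n_spikes)
            y[idx] += signs * channel.spike_amp
            y[np.minimum(idx + 1, len(trace) - 1)] -= signs * channel.spike_amp
    return trace.with_samples(y)
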