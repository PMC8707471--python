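"""Welch power spectral density and alpha/beta drowsiness scoring.

The Welch estimator is written out explicitly because it is the analytic core
of the EEG stage.  A length-N sequence x[n] is cut into K overlapping
segments of length M with hop D,

    x_i[n] = x[n + iD],   n = 0..M-1,   i = 0..K-1,   K = floor((N-M)/D) + 1,

each segment is tapered by a window w[n] and turned into a modified
periodogram |DFT(x_i w)|^2 / (M U) with the window power normalisation
U = (1/M) sum w[n]^2, and the PSD estimate is the arithmetic mean of the
modified periodograms.  The implementation uses the one-sided density
convention (power divided by fs, interior bins doubled) so that the integral
of the PSD over [0, fs/2] estimates the signal variance.

Drowsiness scoring compares alpha-band (8-12 Hz) to beta-band (14-25 Hz)
power on 8-second epochs: alpha rises and beta falls as a subject relaxes
towards sleep, so an alpha/beta ratio well above a personal baseline flags
drowsiness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth import ALPHA_BAND, BETA_BAND
from .trace import SignalTrace


@dataclass(frozen=True)
class WelchSpec:
    """Welch estimator parameters: segment length M, hop D, taper, rate."""

    m: int
    d: int
    window: str = "hann"
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not 1 <= self.d <= self.m:
            raise ValueError("hop D must satisfy 1 <= D <= M")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def taper(self) -> np.ndarray:
        if self.window in ("rectangular", "boxcar"):
            return np.ones(self.m)
        w = sps.get_window(self.window, self.m, fftbins=True)
        return np.asarray(w, dtype=float)

    @classmethod
    def for_trace(
        cls, trace: SignalTrace, segment_s: float = 8.0, overlap: float = 0.5,
        window: str = "hann",
    ) -> "WelchSpec":
        """Default analysis spec: 8-s segments with 50% overlap, clipped to
        the trace length."""
        m = min(len(trace), int(round(segment_s * trace.fs)))
        d = max(1, int(round(m * (1.0 - overlap))))
        return cls(m=m, d=d, window=window, fs=trace.fs)


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided PSD: frequency grid (Hz) and density (units^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray
    spec: WelchSpec | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.size != power.size:
            raise ValueError("frequency grid and power must align")
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            raise ValueError("frequency grid must be increasing")
        if np.any(power < -1e-12):
            raise ValueError("power density must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.freqs))


def segment(x: np.ndarray, m: int, d: int) -> np.ndarray:
    """Cut x into overlapping segments x_i[n] = x[n + iD].

    Returns a (K, M) array with K = floor((N - M)/D) + 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if m > n:
        raise ValueError(f"segment length M={m} exceeds signal length N={n}")
    if not 1 <= d <= m:
        raise ValueError("hop D must satisfy 1 <= D <= M")
    k = (n - m) // d + 1
    return np.stack([x[i * d : i * d + m] for i in range(k)])


def modified_periodogram(
    seg: np.ndarray, window: np.ndarray, fs: float
) -> PsdEstimate:
    """Windowed periodogram |DFT(x w)|^2 / (M U fs), one-sided.

    U = (1/M) sum w[n]^2 normalises the window power; interior bins are
    doubled so the density integrates to the segment's power. A rectangular
    window (U = 1) reduces to the plain periodogram.
    """
    seg = np.asarray(seg, dtype=float)
    window = np.asarray(window, dtype=float)
    if seg.shape != window.shape:
        raise ValueError("window length must equal segment length")
    m = seg.size
    u = float(np.sum(window**2)) / m
    if u == 0:
        raise ValueError("window has zero energy")
    spec = np.fft.rfft(seg * window)
    p = np.abs(spec) ** 2 / (m * u * fs)
    # one-sided: double every bin except DC and (for even M) Nyquist
    if m % 2 == 0:
        p[1:-1] *= 2.0
    else:
        p[1:] *= 2.0
    freqs = np.fft.rfftfreq(m, d=1.0 / fs)
    return PsdEstimate(freqs, p)


def welch_psd(trace: SignalTrace | np.ndarray, spec: WelchSpec) -> PsdEstimate:
    """Welch PSD: mean of modified periodograms over overlapping segments."""
    x = trace.samples if isinstance(trace, SignalTrace) else np.asarray(trace)
    segs = segment(x, spec.m, spec.d)
    window = spec.taper()
    acc = None
    freqs = None
    for seg_i in segs:
        est = modified_periodogram(seg_i, window, spec.fs)
        freqs = est.freqs
        acc = est.power if acc is None else acc + est.power
    power = acc / segs.shape[0]
    return PsdEstimate(freqs, power, spec)


def band_power(psd: PsdEstimate, f_lo: float, f_hi: float) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi].

    Band edges that fall between grid points are handled by linear
    interpolation, so disjoint bands partitioning [0, fs/2] sum exactly to
    the total power.
    """
    if not 0 <= f_lo < f_hi:
        raise ValueError("need 0 <= f_lo < f_hi")
    if psd.freqs.size == 0:
        return 0.0
    f_hi = min(f_hi, float(psd.freqs[-1]))
    f_lo = max(f_lo, float(psd.freqs[0]))
    if f_lo >= f_hi:
        return 0.0
    inner = psd.freqs[(psd.freqs > f_lo) & (psd.freqs < f_hi)]
    grid = np.concatenate(([f_lo], inner, [f_hi]))
    vals = np.interp(grid, psd.freqs, psd.power)
    return float(np.trapezoid(vals, grid))


@dataclass(frozen=True)
class BandPower:
    """Alpha/beta band powers for one epoch (units^2, integrated density)."""

    alpha_power: float
    beta_power: float
    alpha_band: tuple[float, float] = ALPHA_BAND
    beta_band: tuple[float, float] = BETA_BAND

    @property
    def ratio(self) -> float:
        """alpha/beta power ratio; inf when beta power vanishes."""
        if self.beta_power == 0:
            return math.inf if self.alpha_power > 0 else 0.0
        return self.alpha_power / self.beta_power


def epoch_band_power(
    eeg_epoch: SignalTrace,
    alpha_band: tuple[float, float] = ALPHA_BAND,
    beta_band: tuple[float, float] = BETA_BAND,
    segment_s: float = 8.0,
) -> BandPower:
    """Welch band powers of one EEG epoch in the alpha and beta bands."""
    spec = WelchSpec.for_trace(eeg_epoch, segment_s=segment_s)
    psd = welch_psd(eeg_epoch, spec)
    return BandPower(
        alpha_power=band_power(psd, *alpha_band),
        beta_power=band_power(psd, *beta_band),
        alpha_band=alpha_band,
        beta_band=beta_band,
    )


@dataclass(frozen=True)
class DrowsinessScore:
    """Alpha/beta ratio of an epoch against a personal baseline.

    ``drowsy`` is true when ratio > threshold_mult * baseline ratio;
    ``indeterminate`` marks epochs whose beta power vanished (no denominator)
    rather than raising a division error.
    """

    ratio: float
    baseline_ratio: float
    drowsy: bool
    epoch_s: float = 8.0
    indeterminate: bool = False


def drowsiness_score(
    eeg_epoch: SignalTrace,
    baseline: BandPower,
    threshold_mult: float = 1.5,
) -> DrowsinessScore:
    """Score one epoch against an eyes-open baseline band-power pair."""
    bp = epoch_band_power(
        eeg_epoch, alpha_band=baseline.alpha_band, beta_band=baseline.beta_band
    )
    epoch_s = eeg_epoch.duration_s
    if bp.beta_power == 0 or not math.isfinite(baseline.ratio):
        return DrowsinessScore(
            ratio=math.inf if bp.alpha_power > 0 else 0.0,
            baseline_ratio=baseline.ratio,
            drowsy=False,
            epoch_s=epoch_s,
            indeterminate=True,
        )
    ratio = bp.ratio
    return DrowsinessScore(
        ratio=ratio,
        baseline_ratio=baseline.ratio,
        drowsy=ratio > threshold_mult * baseline.ratio,
        epoch_s=epoch_s,
    )
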