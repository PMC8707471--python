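"""R-peak detection, heart rate and rhythm statistics.

The detector follows the classic derivative-square-integrate recipe
(Pan-Tompkins family): band-pass to the QRS band, differentiate, square,
integrate over a ~150 ms moving window, then pick peaks with a 250 ms
refractory period and an adaptive threshold at half the running median of
integrated peak heights.  The threshold is relative, so detection is
invariant to positive rescaling of the input.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .trace import SignalTrace

REFRACTORY_S = 0.25
MIN_RR_S = 0.25  # physiological floor (240 bpm)


@dataclass(frozen=True)
class BeatSeries:
    """Detected R peaks and derived rate/rhythm statistics."""

    r_indices: np.ndarray  # sample positions, strictly increasing
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.r_indices, dtype=int)
        object.__setattr__(self, "r_indices", idx)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("R indices must be strictly increasing")

    def __len__(self) -> int:
        return self.r_indices.size

    @property
    def rr_s(self) -> np.ndarray:
        """Inter-beat intervals in seconds."""
        return np.diff(self.r_indices) / self.fs

    @property
    def hr_bpm(self) -> float:
        """Mean heart rate, 60 / mean RR; NaN with fewer than two beats."""
        rr = self.rr_s
        return float(60.0 / np.mean(rr)) if rr.size else float("nan")

    @property
    def irregularity(self) -> float:
        """Coefficient of variation of RR intervals (0 for steady rhythm)."""
        rr = self.rr_s
        if rr.size < 2:
            return 0.0
        return float(np.std(rr) / np.mean(rr))


def detect_r_peaks(trace: SignalTrace) -> BeatSeries:
    """Locate R peaks on a conditioned ECG trace (fs >= 250 Hz).

    Returns an empty series (with a warning) when the trace is too short or
    too flat to contain two beats.
    """
    if trace.fs < 250:
        raise ValueError("R-peak detection requires fs >= 250 Hz")
    x = trace.samples
    empty = BeatSeries(np.array([], dtype=int), trace.fs)
    if len(x) < int(2 * MIN_RR_S * trace.fs) or np.ptp(x) == 0:
        warnings.warn("trace too short or flat for R-peak detection")
        return empty

    # QRS emphasis: 5-15 Hz band-pass, derivative, square, 150 ms integration
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=trace.fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(0.150 * trace.fs))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    distance = max(1, int(REFRACTORY_S * trace.fs))
    cands, _ = sps.find_peaks(integ, distance=distance)
    if cands.size == 0:
        warnings.warn("no candidate peaks found")
        return empty
    # adaptive threshold: half the running median of accepted integrated
    # peak heights, seeded with a robust estimate of the QRS level (the
    # candidate list also contains low inter-beat bumps, so a plain median
    # would sit far below the QRS cluster)
    ref = float(np.percentile(integ[cands], 90))
    recent: deque[float] = deque(maxlen=8)
    peaks = []
    for p in cands:
        level = float(np.median(recent)) if recent else ref
        if integ[p] >= 0.5 * level:
            peaks.append(p)
            recent.append(float(integ[p]))
    peaks = np.array(peaks, dtype=int)
    if peaks.size == 0:
        return empty

    # refine each detection to the raw-signal maximum within +/-100 ms
    half = int(0.100 * trace.fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    r_idx = np.unique(refined)
    # enforce the refractory period after refinement
    keep = [int(r_idx[0])] if r_idx.size else []
    for p in r_idx[1:]:
        if p - keep[-1] >= distance:
            keep.append(int(p))
    return BeatSeries(np.array(keep, dtype=int), trace.fs)


@dataclass(frozen=True)
class RateBands:
    """Heart-rate bands; boundaries are half-open [lo, hi) and configurable.

    Defaults: normal 70-90 bpm; the maximal-violation (red) candidates are
    40-60 and 100-120 bpm, extended to anything below 40 or above 120.
    """

    normal: tuple[float, float] = (70.0, 90.0)
    red_low: tuple[float, float] = (40.0, 60.0)
    red_high: tuple[float, float] = (100.0, 120.0)
    arrhythmia_cv: float = 0.15


@dataclass(frozen=True)
class RateClassification:
    label: str  # normal | yellow_rate | red_rate
    red_candidate: bool  # inside a maximal-violation band
    arrhythmia: bool
    hr_bpm: float


def classify_rate(beats: BeatSeries, bands: RateBands | None = None) -> RateClassification:
    """Band a beat series.

    A rate inside the 100-120 bpm overlap is labelled ``yellow_rate`` with
    ``red_candidate=True``: the yellow criterion ("over 100") and the red
    candidate band (100-120) overlap by design, and red standing requires a
    second violated metric, which is the alert engine's decision. Rates below
    40 or above 120 are unambiguously ``red_rate``.
    """
    if bands is None:
        bands = RateBands()
    if len(beats) == 0:
        raise ValueError("cannot classify an empty beat series")
    hr = beats.hr_bpm
    arr = beats.irregularity > bands.arrhythmia_cv
    lo, hi = bands.normal
    in_red = (
        bands.red_low[0] <= hr < bands.red_low[1]
        or bands.red_high[0] <= hr < bands.red_high[1]
    )
    if hr < bands.red_low[0] or hr >= bands.red_high[1]:
        return RateClassification("red_rate", True, arr, hr)
    if lo <= hr < hi:
        return RateClassification("normal", False, arr, hr)
    return RateClassification("yellow_rate", in_red, arr, hr)
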