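"""Uniformly sampled single-channel time series.

`SignalTrace` is the carrier for every acquired or synthesised signal in the
package: EEG in microvolts, ECG in millivolts, PPG in arbitrary photodetector
intensity.  The default acquisition rate throughout is 1 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled signal.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes. Units depend on the channel (uV for EEG, mV for ECG,
        arbitrary intensity for PPG).
    fs : float
        Sampling rate in Hz. Must be positive.
    channel : str
        Free-form channel label, e.g. ``"ecg"`` or ``"eeg_occipital"``.
    units : str
        Unit string carried through I/O, e.g. ``"mV"``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channel: str = ""
    units: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "SignalTrace":
        """Copy of this trace with new samples (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))

    def slice_time(self, start_s: float, stop_s: float) -> "SignalTrace":
        """Sub-trace covering [start_s, stop_s) in stream time."""
        i0 = max(0, int(round((start_s - self.t0) * self.fs)))
        i1 = min(len(self), int(round((stop_s - self.t0) * self.fs)))
        return replace(
            self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs
        )


DEFAULT_FS = 1000.0
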