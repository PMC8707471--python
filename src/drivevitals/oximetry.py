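"""SpO2 estimation from dual-wavelength photoplethysmography.

A pulse oximeter shines red (660 nm) and infrared (910 nm) light through
perfused tissue.  The steady (DC) absorption comes from skin, venous blood and
tissue; the pulsatile (AC) component tracks the arterial pulse, whose
absorption depends on the ratio of oxyhaemoglobin HbO2 to reduced
haemoglobin Hb.  SpO2 = HbO2 / (HbO2 + Hb).  The device-level observable is
the ratio of ratios

    R = log(I_AC_R / I_DC_R) / log(I_AC_IR / I_DC_IR)

which is mapped to a saturation percentage through a monotone calibration
table (in hardware oximeters this table lives in EEPROM; here it is a CSV /
in-code default).  Note the log-ratio form: both logs are negative since
AC < DC, so R is positive, and *larger* R means *lower* saturation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .synth import PpgPair


class SensorFaultError(ValueError):
    """Raised when the photodetector signal is physically implausible."""


@dataclass(frozen=True)
class PulsatileComponents:
    """AC/DC intensity decomposition of a red/infrared PPG pair.

    AC is the mean beat-wise peak-to-trough amplitude, DC the windowed mean.
    """

    i_ac_red: float
    i_dc_red: float
    i_ac_ir: float
    i_dc_ir: float

    def __post_init__(self) -> None:
        if self.i_dc_red <= 0 or self.i_dc_ir <= 0:
            raise SensorFaultError("DC intensity must be positive")
        if self.i_ac_red < 0 or self.i_ac_ir < 0:
            raise ValueError("AC amplitude cannot be negative")


@dataclass(frozen=True)
class CalibrationTable:
    """Monotone R -> SpO2 lookup, interpolated piecewise-linearly.

    ``r`` must be strictly increasing and ``spo2`` strictly decreasing
    (higher ratio-of-ratios means lower saturation).
    """

    r: np.ndarray
    spo2: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        spo2 = np.asarray(self.spo2, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "spo2", spo2)
        if r.size == 0:
            raise ValueError("calibration table is empty")
        if r.size != spo2.size:
            raise ValueError("R and SpO2 columns differ in length")
        if not np.all(np.diff(r) > 0):
            raise ValueError("R knots must be strictly increasing")
        if not np.all(np.diff(spo2) < 0):
            raise ValueError("SpO2 knots must be strictly decreasing")
        if np.any(spo2 <= 0) or np.any(spo2 > 100):
            raise ValueError("SpO2 knots must lie in (0, 100]")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]]) -> "CalibrationTable":
        arr = np.asarray(pairs, dtype=float)
        return cls(arr[:, 0], arr[:, 1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["R"].to_numpy(), df["spo2"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"R": self.r, "spo2": self.spo2}).to_csv(path, index=False)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.r[0]), float(self.r[-1])

    def spo2_at(self, r_value: float) -> float:
        """Interpolated SpO2 for a ratio value (clamped with a warning)."""
        lo, hi = self.domain
        if r_value < lo or r_value > hi:
            warnings.warn(
                f"R={r_value:.3f} outside calibration domain [{lo:.3f}, {hi:.3f}]; clamping",
                stacklevel=2,
            )
            r_value = min(max(r_value, lo), hi)
        return float(np.interp(r_value, self.r, self.spo2))

    def r_for_spo2(self, spo2_pct: float) -> float:
        """Inverse lookup used by the synthetic PPG generator."""
        s_lo, s_hi = float(self.spo2[-1]), float(self.spo2[0])
        if not s_lo <= spo2_pct <= s_hi:
            raise ValueError(
                f"SpO2 {spo2_pct}% outside calibration range [{s_lo}, {s_hi}]"
            )
        # spo2 is decreasing in r; flip for np.interp
        return float(np.interp(spo2_pct, self.spo2[::-1], self.r[::-1]))


#: Documented default calibration curve: seven knots spanning 70-100 % SpO2,
#: monotone in the log-ratio R. This is a synthetic stand-in for a device
#: EEPROM table (real tables are per-device trade secrets); the generator
#: inverts whatever table is configured, so round-trip behaviour is
#: table-independent.
DEFAULT_TABLE_KNOTS: tuple[tuple[float, float], ...] = (
    (0.90, 100.0),
    (1.00, 97.0),
    (1.10, 94.0),
    (1.20, 90.0),
    (1.35, 85.0),
    (1.55, 78.0),
    (1.75, 70.0),
)


def default_calibration_table() -> CalibrationTable:
    return CalibrationTable.from_pairs(DEFAULT_TABLE_KNOTS)


def extract_ac_dc(ppg: "PpgPair", window_s: float | None = None) -> PulsatileComponents:
    """Split each PPG channel into DC (windowed mean) and AC components.

    AC is the mean peak-to-trough amplitude over detected beats; the window
    must contain at least two beats for the beat-wise estimate to exist (with
    fewer, a max-min fallback is used and a warning issued).
    """
    red, ir = ppg.red, ppg.ir
    if window_s is not None:
        n = int(window_s * red.fs)
        red = red.with_samples(red.samples[:n])
        ir = ir.with_samples(ir.samples[:n])
    return PulsatileComponents(
        i_ac_red=_ac_amplitude(red.samples, red.fs),
        i_dc_red=float(np.mean(red.samples)),
        i_ac_ir=_ac_amplitude(ir.samples, ir.fs),
        i_dc_ir=float(np.mean(ir.samples)),
    )


def _ac_amplitude(x: np.ndarray, fs: float) -> float:
    """Mean beat-wise peak-to-trough amplitude of a pulsatile signal."""
    ac = x - np.mean(x)
    if np.ptp(ac) == 0:
        return 0.0
    dist = max(1, int(0.3 * fs))  # refractory: max ~200 bpm
    peaks, _ = find_peaks(ac, distance=dist, prominence=0.25 * np.ptp(ac))
    if len(peaks) < 2:
        warnings.warn("fewer than 2 beats in window; using max-min AC estimate")
        return float(np.ptp(ac))
    amps = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        trough = np.min(x[a:b])
        amps.append(0.5 * ((x[a] - trough) + (x[b] - trough)))
    return float(np.mean(amps))


def ratio_R(pc: PulsatileComponents) -> float:
    """Ratio of ratios R = log(AC_R/DC_R) / log(AC_IR/DC_IR).

    Returns NaN (indeterminate) if either AC component is zero — there is no
    pulse to measure. Raises if a modulation ratio is >= 1 (AC must be a
    fraction of DC for the logs to be negative and the ratio meaningful).
    """
    if pc.i_ac_red == 0 or pc.i_ac_ir == 0:
        warnings.warn("zero AC amplitude: ratio-of-ratios indeterminate")
        return math.nan
    m_red = pc.i_ac_red / pc.i_dc_red
    m_ir = pc.i_ac_ir / pc.i_dc_ir
    if m_red >= 1 or m_ir >= 1:
        raise ValueError("AC amplitude must be smaller than DC level")
    return math.log(m_red) / math.log(m_ir)


def spo2_from_ratio(r_value: float, table: CalibrationTable | None = None) -> float:
    """Map a ratio-of-ratios value to SpO2 % through the calibration table."""
    if table is None:
        table = default_calibration_table()
    return table.spo2_at(r_value)


@dataclass(frozen=True)
class Spo2Estimate:
    """Full-pipeline oximetry result for one analysis window."""

    spo2_pct: float
    r_value: float
    components: PulsatileComponents
    indeterminate: bool


def estimate_spo2(
    ppg: "PpgPair",
    table: CalibrationTable | None = None,
    window_s: float | None = None,
) -> Spo2Estimate:
    """AC/DC extraction -> ratio of ratios -> table lookup, in one call."""
    pc = extract_ac_dc(ppg, window_s=window_s)
    r_value = ratio_R(pc)
    if math.isnan(r_value):
        return Spo2Estimate(math.nan, r_value, pc, indeterminate=True)
    return Spo2Estimate(spo2_from_ratio(r_value, table), r_value, pc, False)


def smooth_spo2(values: Sequence[float], window: int = 3) -> list[float]:
    """Running median over the trailing ``window`` estimates.

    Applied before alerting so a single noisy window cannot flip the
    saturation band. NaN (indeterminate) windows are ignored.
    """
    out: list[float] = []
    for i in range(len(values)):
        chunk = [v for v in values[max(0, i - window + 1) : i + 1] if not math.isnan(v)]
        out.append(float(np.median(chunk)) if chunk else math.nan)
    return out
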