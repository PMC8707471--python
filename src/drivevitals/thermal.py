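"""8x8 thermal-array analysis: cabin overheat and flame detection.

A Grid-EYE style thermopile array reports 64 surface temperatures per frame.
A parked cabin can reach a critical 40 C in roughly eight minutes on a summer
day, which sets the default warming-rate threshold (~0.04 C/s); flames show
up as localized pixels with large frame-to-frame jumps.  Classification
precedence is flame > overheat > warming > ambient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

GRID_SHAPE = (8, 8)
TEMP_RANGE_C = (-20.0, 1000.0)

THERMAL_LABELS = ("ambient", "warming", "overheat", "flame")
_SEVERITY = {label: i for i, label in enumerate(THERMAL_LABELS)}


@dataclass(frozen=True)
class ThermalFrame:
    """One timestamped 8x8 grid of surface temperatures in Celsius."""

    temps: np.ndarray
    time_s: float

    def __post_init__(self) -> None:
        temps = np.asarray(self.temps, dtype=float)
        if temps.size != 64:
            raise ValueError(f"thermal frame must have 64 values, got {temps.size}")
        temps = temps.reshape(GRID_SHAPE)
        if not np.all(np.isfinite(temps)):
            raise ValueError("thermal frame contains non-finite values")
        lo, hi = TEMP_RANGE_C
        if temps.min() < lo or temps.max() > hi:
            raise ValueError(f"temperatures outside plausible range {TEMP_RANGE_C} C")
        object.__setattr__(self, "temps", temps)


@dataclass(frozen=True)
class ThermalConfig:
    """Thresholds for the overheat/flame classifier.

    warn_temp < critical_temp < flame_temp is enforced. ``regions`` maps a
    name to a boolean 8x8 mask (row-major pixel indexing p(row)(col)).
    """

    warn_temp: float = 35.0
    critical_temp: float = 40.0
    flame_temp: float = 60.0
    flame_jump: float = 15.0  # C per frame
    warming_rate: float = 0.04  # C/s
    min_rise_c: float = 0.5  # fitted rise needed before 'warming' flags
    gradient_window: int = 60  # frames
    regions: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.warn_temp < self.critical_temp < self.flame_temp:
            raise ValueError("require warn_temp < critical_temp < flame_temp")
        for name, mask in self.regions.items():
            m = np.asarray(mask, dtype=bool)
            if m.shape != GRID_SHAPE:
                raise ValueError(f"region {name!r} mask must be 8x8")


@dataclass(frozen=True)
class RegionStats:
    max_c: float
    mean_c: float
    argmax: tuple[int, int]  # (row, col)


def frame_stats(
    frame: ThermalFrame, regions: Mapping[str, np.ndarray] | None = None
) -> dict[str, RegionStats]:
    """Per-region max/mean/argmax; the whole grid appears under ``"frame"``."""
    out: dict[str, RegionStats] = {}
    masks: dict[str, np.ndarray] = {"frame": np.ones(GRID_SHAPE, dtype=bool)}
    for name, mask in (regions or {}).items():
        m = np.asarray(mask, dtype=bool)
        if m.shape != GRID_SHAPE:
            raise ValueError(f"region {name!r} references pixels outside the 8x8 grid")
        if not m.any():
            raise ValueError(f"region {name!r} is empty")
        masks[name] = m
    for name, m in masks.items():
        vals = frame.temps[m]
        rows, cols = np.nonzero(m)
        k = int(np.argmax(vals))
        out[name] = RegionStats(
            max_c=float(vals.max()),
            mean_c=float(vals.mean()),
            argmax=(int(rows[k]), int(cols[k])),
        )
    return out


def temporal_gradient(
    frames: Sequence[ThermalFrame], window: int | None = None
) -> np.ndarray:
    """Per-pixel least-squares temperature slope in C/s over the last frames."""
    if len(frames) < 2:
        raise ValueError("need at least 2 frames for a temporal gradient")
    t = np.array([f.time_s for f in frames])
    if not np.all(np.diff(t) > 0):
        raise ValueError("frame timestamps must be strictly increasing")
    if window is not None:
        frames = frames[-window:]
        t = t[-window:]
    x = np.stack([f.temps for f in frames])  # (n, 8, 8)
    tc = t - t.mean()
    denom = float(np.sum(tc**2))
    xc = x - x.mean(axis=0)
    return np.tensordot(tc, xc, axes=(0, 0)) / denom


@dataclass(frozen=True)
class ThermalClassification:
    label: str  # one of THERMAL_LABELS
    trigger_pixels: tuple[tuple[int, int], ...]

    @property
    def severity(self) -> int:
        return _SEVERITY[self.label]


def classify_thermal(
    frames: Sequence[ThermalFrame], config: ThermalConfig | None = None
) -> ThermalClassification:
    """Classify a frame sequence as ambient / warming / overheat / flame.

    flame: any pixel jumps upward by >= flame_jump between consecutive frames,
    or any pixel in the latest frame exceeds flame_temp.
    overheat: any pixel of the latest frame at or above critical_temp.
    warming: any pixel's temperature slope >= warming_rate.
    Precedence: flame > overheat > warming > ambient.
    """
    if config is None:
        config = ThermalConfig()
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to classify")
    stack = np.stack([f.temps for f in frames])
    latest = stack[-1]

    jumps = np.diff(stack, axis=0)  # positive = heating
    jump_mask = (jumps >= config.flame_jump).any(axis=0)
    hot_mask = latest >= config.flame_temp
    flame_mask = jump_mask | hot_mask
    if flame_mask.any():
        return ThermalClassification("flame", _pixels(flame_mask))

    over_mask = latest >= config.critical_temp
    if over_mask.any():
        return ThermalClassification("overheat", _pixels(over_mask))

    sub = frames[-config.gradient_window :]
    grad = temporal_gradient(sub)
    # require both a sufficient rate and a sufficient fitted total rise, so
    # per-pixel sensor noise on short windows cannot fake a warming slope
    span = sub[-1].time_s - sub[0].time_s
    warm_mask = (grad >= config.warming_rate) & (grad * span >= config.min_rise_c)
    if warm_mask.any():
        return ThermalClassification("warming", _pixels(warm_mask))

    return ThermalClassification("ambient", ())


def _pixels(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    rows, cols = np.nonzero(mask)
    return tuple((int(r), int(c)) for r, c in zip(rows, cols))
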