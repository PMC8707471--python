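"""Five-phase driver-state alert engine and e-Call payload assembly.

The cooperative-driving alert logic runs over a stream of fused vitals
snapshots and assigns one of five phases:

1. training   — personal baselines are being learned; no alerting.
2. green      — all metrics inside their normal bands.
3. yellow     — a single metric beyond normal, sustained over a declared
                persistence window (e.g. pulse over 100, SpO2 94-90).
4. red        — at least two metrics sustained in their maximal-violation
                bands (pulse 40-60 or 100-120, SpO2 below 90, detected
                arrhythmia, detected drowsiness).
5. collision  — an impact was observed; the pre-impact ring buffer is
                packaged into an e-Call payload for the rescue chain.

A lone heart rate of 110 bpm is therefore *yellow*, even though 100-120 bpm
is a maximal-violation band: red standing requires a second violated metric.
The evaluation is a pure function of (history, config), so streaming and
batch evaluation agree snapshot for snapshot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict

PHASE_COLORS = {1: "training", 2: "green", 3: "yellow", 4: "red", 5: "collision"}

SEVERITY_NORMAL, SEVERITY_YELLOW, SEVERITY_RED = 0, 1, 2


@dataclass(frozen=True)
class VitalsSnapshot:
    """Per-window fused metrics; ``None`` marks a metric as missing."""

    time_s: float
    hr_bpm: float | None = None
    spo2_pct: float | None = None
    drowsy: bool | None = None
    arrhythmia: bool | None = None
    eeg_state: str | None = None
    thermal_label: str | None = None
    impact: bool = False


@dataclass(frozen=True)
class PhaseConfig:
    """Per-metric bands and timing for the phase machine.

    Heart-rate bands: ``hr_normal`` inclusive; maximal-violation candidates
    are ``hr_red_low`` / ``hr_red_high`` (inclusive), extended to anything
    more extreme. SpO2: normal at or above 95, yellow 90-94, red below 90
    (bounds inclusive as documented). ``persistence_s`` is how long a
    violation must hold before it escalates; ``ring_buffer_s`` is the
    pre-impact retention window.
    """

    hr_normal: tuple[float, float] = (70.0, 90.0)
    hr_red_low: tuple[float, float] = (40.0, 60.0)
    hr_red_high: tuple[float, float] = (100.0, 120.0)
    spo2_normal_min: float = 95.0
    spo2_red_max: float = 90.0  # red strictly below this
    persistence_s: float = 10.0
    ring_buffer_s: float = 30.0
    red_min_metrics: int = 2
    training: bool = False

    def __post_init__(self) -> None:
        if self.persistence_s <= 0:
            raise ValueError("persistence_s must be positive")
        if self.ring_buffer_s <= 0:
            raise ValueError("ring_buffer_s must be positive")

    # -- per-metric banding -------------------------------------------------

    def hr_severity(self, hr: float | None) -> int:
        if hr is None:
            return SEVERITY_NORMAL
        if self.hr_normal[0] <= hr <= self.hr_normal[1]:
            return SEVERITY_NORMAL
        in_red = (
            hr < self.hr_red_low[0]
            or self.hr_red_low[0] <= hr <= self.hr_red_low[1]
            or self.hr_red_high[0] < hr  # over 100, incl. beyond 120
        )
        return SEVERITY_RED if in_red else SEVERITY_YELLOW

    def spo2_severity(self, spo2: float | None) -> int:
        if spo2 is None:
            return SEVERITY_NORMAL
        if spo2 >= self.spo2_normal_min:
            return SEVERITY_NORMAL
        return SEVERITY_RED if spo2 < self.spo2_red_max else SEVERITY_YELLOW

    @staticmethod
    def thermal_severity(label: str | None) -> int:
        if label in ("overheat", "flame"):
            return SEVERITY_RED
        if label == "warming":
            return SEVERITY_YELLOW
        return SEVERITY_NORMAL

    @staticmethod
    def eeg_severity(state: str | None) -> int:
        if state in ("stress", "distraction"):
            return SEVERITY_YELLOW
        return SEVERITY_NORMAL

    def metric_severities(self, snap: VitalsSnapshot) -> dict[str, int]:
        """Severity per metric. The drowsiness and arrhythmia flags each
        count as one maximal-violation metric when set."""
        return {
            "hr": self.hr_severity(snap.hr_bpm),
            "spo2": self.spo2_severity(snap.spo2_pct),
            "drowsy": SEVERITY_RED if snap.drowsy else SEVERITY_NORMAL,
            "arrhythmia": SEVERITY_RED if snap.arrhythmia else SEVERITY_NORMAL,
            "thermal": self.thermal_severity(snap.thermal_label),
            "eeg": self.eeg_severity(snap.eeg_state),
        }


@dataclass(frozen=True)
class AlertDecision:
    """Phase decision for the newest snapshot of a history."""

    phase: int  # 1..5
    color: str
    triggers: tuple[tuple[str, float | str | bool, str], ...]  # (metric, value, band)
    since: float  # stream time the triggering condition has held from
    time_s: float


def calibrate(
    baseline: Sequence[VitalsSnapshot],
    defaults: PhaseConfig | None = None,
    k_sd: float = 3.0,
    min_duration_s: float = 60.0,
) -> PhaseConfig:
    """Learn personal normal bands from a training stream (Phase 1).

    The personalised normal band is mean +/- k_sd standard deviations,
    clipped to stay strictly inside the printed yellow/red boundaries
    (heart rate within (60, 100) bpm; SpO2 floor above 90%). With an
    insufficient baseline the printed defaults are returned with a warning.
    """
    if defaults is None:
        defaults = PhaseConfig()
    span = baseline[-1].time_s - baseline[0].time_s if len(baseline) > 1 else 0.0
    if span < min_duration_s:
        warnings.warn(
            f"baseline covers {span:.0f} s < {min_duration_s:.0f} s; "
            "falling back to default bands"
        )
        return replace(defaults, training=False)
    hr = np.array([s.hr_bpm for s in baseline if s.hr_bpm is not None])
    spo2 = np.array([s.spo2_pct for s in baseline if s.spo2_pct is not None])
    cfg = replace(defaults, training=False)
    if hr.size >= 2:
        lo = max(float(hr.mean() - k_sd * hr.std()), 61.0)
        hi = min(float(hr.mean() + k_sd * hr.std()), 99.0)
        if lo < hi:
            cfg = replace(cfg, hr_normal=(lo, hi))
    if spo2.size >= 2:
        floor = max(float(spo2.mean() - k_sd * spo2.std()), 91.0)
        cfg = replace(cfg, spo2_normal_min=min(floor, cfg.spo2_normal_min))
    return cfg


def _sustained_since(
    history: Sequence[VitalsSnapshot],
    config: PhaseConfig,
    metric: str,
    min_severity: int,
) -> float | None:
    """Stream time since which ``metric`` has continuously been at or above
    ``min_severity``; None if the newest snapshot is below it."""
    since = None
    for snap in reversed(history):
        if config.metric_severities(snap)[metric] >= min_severity:
            since = snap.time_s
        else:
            break
    return since


def _raw_phase_at(
    history: Sequence[VitalsSnapshot], config: PhaseConfig, end: int
) -> tuple[int, list[tuple[str, float | str | bool, str]], float]:
    """Phase from band counts + persistence for history[:end+1]."""
    sub = history[: end + 1]
    last = sub[-1]
    now = last.time_s
    sev = config.metric_severities(last)
    triggers: list[tuple[str, float | str | bool, str]] = []
    red_sustained: list[str] = []
    any_sustained = False
    earliest = now
    for metric, s in sev.items():
        if s == SEVERITY_NORMAL:
            continue
        value = {
            "hr": last.hr_bpm,
            "spo2": last.spo2_pct,
            "drowsy": last.drowsy,
            "arrhythmia": last.arrhythmia,
            "thermal": last.thermal_label,
            "eeg": last.eeg_state,
        }[metric]
        since = _sustained_since(sub, config, metric, SEVERITY_YELLOW)
        sustained = since is not None and now - since >= config.persistence_s
        if sustained:
            any_sustained = True
            earliest = min(earliest, since)
            band = "red" if s == SEVERITY_RED else "yellow"
            triggers.append((metric, value, band))
            if s == SEVERITY_RED:
                red_since = _sustained_since(sub, config, metric, SEVERITY_RED)
                if red_since is not None and now - red_since >= config.persistence_s:
                    red_sustained.append(metric)
    if len(red_sustained) >= config.red_min_metrics:
        return 4, triggers, earliest
    if any_sustained:
        return 3, triggers, earliest
    return 2, [], now


def evaluate(
    history: Sequence[VitalsSnapshot], config: PhaseConfig | None = None
) -> AlertDecision:
    """Pure phase decision for the newest snapshot of a time-ordered history.

    An observed impact forces phase 5 regardless of vitals. Otherwise the
    phase is the maximum banded phase over the trailing persistence window
    (de-escalation hysteresis: metrics must be back in band for a full
    persistence window before the phase relaxes).
    """
    if config is None:
        config = PhaseConfig()
    if not history:
        raise ValueError("history must be non-empty")
    times = [s.time_s for s in history]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("history must be time-ordered")
    last = history[-1]
    if any(s.impact for s in history):
        t_imp = next(s.time_s for s in history if s.impact)
        return AlertDecision(
            5, PHASE_COLORS[5], (("impact", True, "collision"),), t_imp, last.time_s
        )
    if config.training:
        return AlertDecision(1, PHASE_COLORS[1], (), times[0], last.time_s)
    phase, triggers, since = _raw_phase_at(history, config, len(history) - 1)
    # hysteresis: hold the highest phase banded within the last persistence_s
    for i in range(len(history) - 2, -1, -1):
        if last.time_s - history[i].time_s > config.persistence_s:
            break
        p_i, trig_i, since_i = _raw_phase_at(history, config, i)
        if p_i > phase:
            phase, triggers, since = p_i, trig_i, since_i
    return AlertDecision(phase, PHASE_COLORS[phase], tuple(triggers), since, last.time_s)


class AlertStream:
    """Streaming wrapper: feed snapshots one by one, get per-snapshot
    decisions identical to batch evaluation of the accumulated history."""

    def __init__(self, config: PhaseConfig | None = None) -> None:
        self.config = config or PhaseConfig()
        self.history: list[VitalsSnapshot] = []

    def push(self, snapshot: VitalsSnapshot) -> AlertDecision:
        self.history.append(snapshot)
        return evaluate(self.history, self.config)


# ---------------------------------------------------------------------------
# Ring buffer and e-Call payload
# ---------------------------------------------------------------------------


def update_ring_buffer(
    buffer: Sequence[VitalsSnapshot],
    snapshot: VitalsSnapshot,
    ring_buffer_s: float = 30.0,
) -> list[VitalsSnapshot]:
    """Append a snapshot and retain those within ``ring_buffer_s`` of it.

    The boundary is inclusive: a snapshot exactly ``ring_buffer_s`` old is
    kept (so 60 s of 1 Hz snapshots with a 30 s buffer retains 31).
    """
    if buffer and snapshot.time_s < buffer[-1].time_s:
        raise ValueError("snapshot times must be monotone")
    out = [*buffer, snapshot]
    cutoff = snapshot.time_s - ring_buffer_s
    return [s for s in out if s.time_s >= cutoff]


class SnapshotModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time_s: float
    hr_bpm: float | None = None
    spo2_pct: float | None = None
    drowsy: bool | None = None
    arrhythmia: bool | None = None
    eeg_state: str | None = None
    thermal_label: str | None = None
    impact: bool = False


class VehicleDynamics(BaseModel):
    """Placeholders for pre-impact vehicle dynamics; unavailable fields stay
    null but are never omitted from the payload."""

    model_config = ConfigDict(extra="forbid")
    speed_kmh: float | None = None
    heading_deg: float | None = None


class ECallPayload(BaseModel):
    """Minimum data set handed to the emergency chain after a collision."""

    model_config = ConfigDict(extra="forbid")
    schema_version: str = "1.0"
    vehicle_id: str
    occupant_count: int
    timestamp_s: float
    position: tuple[float, float] | None  # (lat, lon)
    dynamics: VehicleDynamics
    pre_impact_snapshots: list[SnapshotModel]

    def to_json(self) -> str:
        return self.model_dump_json()

    @classmethod
    def from_json(cls, text: str) -> "ECallPayload":
        return cls.model_validate_json(text)


def build_ecall_payload(
    buffer: Sequence[VitalsSnapshot],
    vehicle_id: str,
    occupant_count: int,
    position: tuple[float, float] | None = None,
    dynamics: VehicleDynamics | None = None,
    timestamp_s: float | None = None,
) -> ECallPayload:
    """Assemble the phase-5 payload from the pre-impact ring buffer."""
    if not vehicle_id:
        raise ValueError("vehicle_id is required for an e-Call payload")
    snaps = [SnapshotModel(**vars(s)) for s in buffer]
    if timestamp_s is None:
        timestamp_s = buffer[-1].time_s if buffer else 0.0
    return ECallPayload(
        vehicle_id=vehicle_id,
        occupant_count=occupant_count,
        timestamp_s=timestamp_s,
        position=position,
        dynamics=dynamics or VehicleDynamics(),
        pre_impact_snapshots=snaps,
    )
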