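"""Run configuration: a schema-validated JSON document.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .alerts import PhaseConfig
from .thermal import ThermalConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ConditioningConfig(_Section):
    notch_hz: float = 50.0
    bandpass: tuple[float, float] = (0.5, 35.0)
    ma_window: int = 5
    wavelet_family: str = "haar"
    wavelet_levels: int = 3
    wavelet_mode: str = "soft"


class EegConfig(_Section):
    alpha_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (14.0, 25.0)
    epoch_s: float = 8.0
    threshold_mult: float = 1.5
    persistence_epochs: int = 2


class EcgConfig(_Section):
    hr_normal: tuple[float, float] = (70.0, 90.0)
    arrhythmia_cv: float = 0.15


class OximetryConfig(_Section):
    table_csv: str | None = None  # default in-code table when None
    smooth_windows: int = 3


class ThermalSection(_Section):
    warn_temp: float = 35.0
    critical_temp: float = 40.0
    flame_temp: float = 60.0
    flame_jump: float = 15.0
    warming_rate: float = 0.04
    min_rise_c: float = 0.5

    def to_thermal_config(self) -> ThermalConfig:
        return ThermalConfig(
            warn_temp=self.warn_temp,
            critical_temp=self.critical_temp,
            flame_temp=self.flame_temp,
            flame_jump=self.flame_jump,
            warming_rate=self.warming_rate,
            min_rise_c=self.min_rise_c,
        )


class AlertingConfig(_Section):
    persistence_s: float = 10.0
    ring_buffer_s: float = 30.0
    vehicle_id: str = "TEST-VEHICLE-001"
    occupant_count: int = 1
    position: tuple[float, float] | None = None
    acknowledgement_mode: str = "suppress"  # suppress | reset

    def to_phase_config(self, **overrides) -> PhaseConfig:
        return PhaseConfig(
            persistence_s=self.persistence_s,
            ring_buffer_s=self.ring_buffer_s,
            **overrides,
        )


class ClassifierConfig(_Section):
    k: int = 12
    gamma: float = 1.0
    hidden: int = 16
    smooth: float = 0.0


class RunConfig(_Section):
    """Top-level configuration; every default is the documented default."""

    seed: int = 0
    fs: float = 1000.0
    window_s: float = 10.0  # tumbling vitals-fusion window
    conditioning: ConditioningConfig = ConditioningConfig()
    eeg: EegConfig = EegConfig()
    ecg: EcgConfig = EcgConfig()
    oximetry: OximetryConfig = OximetryConfig()
    thermal: ThermalSection = ThermalSection()
    alerting: AlertingConfig = AlertingConfig()
    classifier: ClassifierConfig = ClassifierConfig()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))
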