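"""CSV / JSONL dialects for traces, thermal frames and event logs.

Signal CSV: `#`-prefixed header lines carrying ``fs``, ``units``, ``channel``
and ``t0``, then two columns ``time_s,value``.  Thermal CSV: one row per
frame, columns ``time_s,p00..p77`` (row-major pixel indexing p(row)(col)).
Event log: JSON lines, append-only, time-ordered within a run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .thermal import GRID_SHAPE, ThermalFrame
from .trace import SignalTrace


class FormatError(ValueError):
    """Malformed on-disk signal or frame file."""


_PIXEL_COLS = [f"p{r}{c}" for r in range(8) for c in range(8)]


def write_signal_csv(trace: SignalTrace, path: str | Path, precision: int = 9) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={trace.fs!r}\n")
        fh.write(f"# units={trace.units}\n")
        fh.write(f"# channel={trace.channel}\n")
        fh.write(f"# t0={trace.t0!r}\n")
        fh.write("time_s,value\n")
        for t, v in zip(trace.times, trace.samples):
            fh.write(f"{t:.{precision}g},{v:.{precision}g}\n")


def read_signal_csv(path: str | Path) -> SignalTrace:
    path = Path(path)
    header: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
    if "fs" not in header:
        raise FormatError(f"{path}: missing 'fs' header line")
    fs = float(header["fs"])
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df or "value" not in df:
        raise FormatError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy()
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time column must be strictly increasing")
        if not np.allclose(dt, 1.0 / fs, rtol=1e-3, atol=1e-6 / fs):
            raise FormatError(f"{path}: time column not uniform at fs={fs}")
    return SignalTrace(
        df["value"].to_numpy(),
        fs=fs,
        channel=header.get("channel", ""),
        units=header.get("units", ""),
        t0=float(header.get("t0", t[0] if t.size else 0.0)),
    )


def write_thermal_csv(frames: Sequence[ThermalFrame], path: str | Path) -> None:
    rows = []
    for f in frames:
        row = {"time_s": f.time_s}
        row.update(dict(zip(_PIXEL_COLS, f.temps.ravel())))
        rows.append(row)
    pd.DataFrame(rows, columns=["time_s", *_PIXEL_COLS]).to_csv(path, index=False)


def read_thermal_csv(path: str | Path) -> list[ThermalFrame]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("time_s", *_PIXEL_COLS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing[:3]}...")
    return [
        ThermalFrame(row[_PIXEL_COLS].to_numpy(dtype=float).reshape(GRID_SHAPE),
                     time_s=float(row["time_s"]))
        for _, row in df.iterrows()
    ]


@dataclass(frozen=True)
class EventRecord:
    """One event emitted during a monitoring run."""

    time_s: float
    source: str
    severity: str  # info | warning | alert
    payload: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "time_s": self.time_s,
                "source": self.source,
                "severity": self.severity,
                "payload": self.payload,
            },
            sort_keys=True,
        )


def write_events_jsonl(events: Iterable[EventRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ev in events:
            fh.write(ev.to_json() + "\n")


def read_events_jsonl(path: str | Path) -> list[EventRecord]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            d = json.loads(line)
            out.append(EventRecord(d["time_s"], d["source"], d["severity"], d["payload"]))
    return out


def write_psd_csv(freqs: np.ndarray, power: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": freqs, "power": power}).to_csv(path, index=False)
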