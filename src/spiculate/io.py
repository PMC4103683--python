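"""File formats and pipeline configuration.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header row.
Schemas:

* trace CSV — ``time_s,green,red,green_bg,red_bg`` (background columns
  optional once subtracted);
* dff CSV — ``time_s,dff_percent``;
* events JSON — object mapping event name to a list of times in seconds;
* trial table CSV — the documented column schema of
  :data:`spiculate.synthetic.TRIAL_COLUMNS` (semicolon-joined lists within
  cells);
* config YAML — lossless round-trip of :class:`PipelineConfig`.

Malformed rows are reported with their (1-based, header-inclusive) line
number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import DffTrace, DualChannelTrace, EventLog
from .synthetic import TRIAL_COLUMNS

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "read_dff",
    "write_dff",
    "read_trials",
    "write_trials",
    "PipelineConfig",
]

TRACE_COLUMNS = ["time_s", "green", "red", "green_bg", "red_bg"]


def _require_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_trace(path) -> DualChannelTrace:
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, TRACE_COLUMNS[:3], path)
    t = frame["time_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: header line plus 0-based -> 1-based
        raise ValueError(
            f"{path}: time_s not strictly increasing at line {int(bad[0]) + 3}"
        )
    has_bg = all(c in frame.columns for c in ("green_bg", "red_bg"))
    return DualChannelTrace(
        t,
        frame["green"].to_numpy(float),
        frame["red"].to_numpy(float),
        frame["green_bg"].to_numpy(float) if has_bg else None,
        frame["red_bg"].to_numpy(float) if has_bg else None,
    )


def write_trace(trace: DualChannelTrace, path) -> None:
    data = {"time_s": trace.time_s, "green": trace.green, "red": trace.red}
    if trace.has_background:
        data["green_bg"] = trace.green_bg
        data["red_bg"] = trace.red_bg
    # default float repr is shortest-round-trippable, keeping IO lossless
    pd.DataFrame(data).to_csv(path, index=False)


def read_events(path) -> EventLog:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: event file must contain a JSON object")
    return EventLog(raw)


def write_events(events: EventLog, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(events.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_dff(path, events: Optional[EventLog] = None) -> DffTrace:
    frame = pd.read_csv(path, float_precision="round_trip")
    _require_columns(frame, ["time_s", "dff_percent"], path)
    f0 = float(frame.attrs.get("f0", 1.0))
    if "f0" in frame.columns:
        f0 = float(frame["f0"].iloc[0])
    return DffTrace(
        frame["time_s"].to_numpy(float),
        frame["dff_percent"].to_numpy(float),
        f0,
        events or EventLog(),
    )


def write_dff(dff: DffTrace, path) -> None:
    pd.DataFrame(
        {"time_s": dff.time_s, "dff_percent": dff.dff_percent, "f0": dff.f0}
    ).to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=True, float_precision="round_trip")
    _require_columns(frame, TRIAL_COLUMNS, path)
    string_cols = [
        "commence_s", "vulva_contact_start_s", "vulva_contact_end_s",
        "insert_s", "retract_s", "progeny",
    ]
    for col in string_cols:
        frame[col] = frame[col].fillna("")
    return frame


def write_trials(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, round-trippable through YAML."""

    dt_s: float = 0.05
    f0_span_s: float = 2.0
    onset_k: float = 2.0
    onset_m: int = 3
    peak_window_s: float = 30.0
    post_peak_window_s: float = 15.0
    refractory_bins_s: Tuple[float, float, float] = (180.0, 540.0, 1800.0)
    bleach_model: str = "exponential"  # exponential | linear | biexponential
    mw_mode: str = "auto"
    biphasic: bool = False
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        for name in ("dt_s", "f0_span_s", "peak_window_s", "post_peak_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.onset_m < 1:
            raise ValueError("onset_m must be >= 1")
        self.refractory_bins_s = tuple(float(v) for v in self.refractory_bins_s)

    def to_yaml(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        payload["refractory_bins_s"] = list(self.refractory_bins_s)
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        text = (
            Path(source).read_text(encoding="utf-8")
            if isinstance(source, (str, Path)) and "\n" not in str(source)
            else str(source)
        )
        payload = yaml.safe_load(text)
        return cls(**payload)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
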