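"""Model / results objects for event-aligned transient analysis.

:class:`BoutKinetics` wraps the per-bout correction-and-extraction chain
(background subtraction, red-channel bleach fit and correction, ratiometric
%ΔF/F0, kinetic feature extraction); :class:`CohortKinetics` fits a cohort
of bouts and summarises them in the published per-cell-type table layout.
Both follow the fit-then-results convention: the model object holds data and
configuration, ``fit()`` returns an immutable results object with the
estimates, diagnostics, a ``summary()`` table and plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import kinetics as _kin
from . import traces as _tr
from .datatypes import (
    BleachModel,
    DffTrace,
    DualChannelTrace,
    EventLog,
    KineticFeatures,
)
from .io import PipelineConfig, read_events, read_trace

__all__ = [
    "BoutKinetics",
    "BoutKineticsResults",
    "CohortKinetics",
    "CohortKineticsResults",
]


@dataclass(frozen=True)
class BoutKineticsResults:
    """Fitted per-bout results: corrected trace, bleach model, features."""

    dff: DffTrace
    bleach: BleachModel
    features: KineticFeatures
    config: PipelineConfig

    def summary(self) -> str:
        f = self.features
        lines = [
            "Bout kinetics",
            "=" * 44,
            f"samples                 {len(self.dff):>10d}",
            f"baseline F0 (ratio)     {self.dff.f0:>10.4f}",
        ]
        if self.bleach.degenerate:
            lines.append("red bleach              constant (no decay)")
        else:
            lines.append(f"red bleach tau (s)      {self.bleach.tau_s:>10.2f}")
        def fmt(v, unit=""):
            return "undefined" if v is None else f"{v:10.3f}{unit}"
        lines += [
            f"onset (s)               {fmt(f.onset_s)}",
            f"insertion→peak (s)      {fmt(f.insertion_to_peak_s)}",
            f"peak ΔF/F0 (%)          {fmt(f.peak_dff)}",
            f"rise slope (%/s)        {fmt(f.rise_slope)}",
            f"post-peak 15 s slope    {fmt(f.post_peak_15s_slope)}",
        ]
        if f.second_peak_time_s is not None:
            lines += [
                f"2nd-rise onset (s)      {fmt(f.second_rise_onset_s)}",
                f"2nd peak time (s)       {fmt(f.second_peak_time_s)}",
                f"2nd-rise slope (%/s)    {fmt(f.second_rise_slope)}",
            ]
        if f.flags:
            lines.append(f"flags: {', '.join(f.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the %ΔF/F0 trace with event and feature annotations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        ax.plot(self.dff.time_s, self.dff.dff_percent, lw=0.8, color="forestgreen")
        for name, times in self.dff.events.items():
            for t in times:
                ax.axvline(t, color="gray", ls="--", lw=0.6)
                ax.text(t, ax.get_ylim()[1], name, rotation=90, fontsize=6, va="top")
        if self.features.peak_time_s is not None:
            ax.plot(
                self.features.peak_time_s, self.features.peak_dff, "v", color="crimson"
            )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("%ΔF/F0")
        return ax


@dataclass
class BoutKinetics:
    """Per-bout model: raw dual-channel trace + event log + configuration."""

    trace: DualChannelTrace
    events: EventLog = field(default_factory=EventLog)
    config: PipelineConfig = field(default_factory=PipelineConfig)

    @classmethod
    def from_csv(cls, trace_path, events_path=None, config=None) -> "BoutKinetics":
        events = read_events(events_path) if events_path else EventLog()
        return cls(read_trace(trace_path), events, config or PipelineConfig())

    def fit(self) -> BoutKineticsResults:
        cfg = self.config
        trace = self.trace
        if trace.has_background:
            trace = _tr.subtract_background(trace)
        bleach = _tr.fit_bleach_decay(trace.red, trace.time_s)
        window = _tr.default_f0_window(trace.time_s, self.events, cfg.f0_span_s)
        dff = _tr.ratiometric_dff(trace, bleach, window, self.events)
        features = _kin.extract_features(
            dff,
            search_window_s=cfg.peak_window_s,
            k=cfg.onset_k,
            m=cfg.onset_m,
            biphasic=cfg.biphasic,
        )
        return BoutKineticsResults(dff, bleach, features, cfg)


@dataclass(frozen=True)
class CohortKineticsResults:
    """Cohort results: per-bout feature table and the summary row."""

    group: str
    bout_results: Tuple[BoutKineticsResults, ...]
    features_frame: pd.DataFrame
    summary_frame: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.bout_results)

    def summary(self) -> str:
        row = self.summary_frame.iloc[0]
        return (
            f"Cohort '{self.group}' (n = {self.n})\n"
            + "=" * 44 + "\n"
            f"insertion→peak (s)      {row['latency_label']}\n"
            f"initial rise slope (%/s) {row['slope_label']}\n"
        )


@dataclass
class CohortKinetics:
    """Cohort model over (trace, events) pairs sharing one configuration."""

    bouts: Sequence[Tuple[DualChannelTrace, EventLog]]
    group: str = ""
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def fit(self) -> CohortKineticsResults:
        if not self.bouts:
            raise ValueError("cohort contains no bouts")
        results = [
            BoutKinetics(trace, events, self.config).fit()
            for trace, events in self.bouts
        ]
        features = [r.features for r in results]
        frame = pd.DataFrame([f.to_dict() for f in features])
        frame.insert(0, "bout", range(len(features)))
        summary = _kin.summarize_cohort(features, self.group)
        return CohortKineticsResults(self.group, tuple(results), frame, summary)
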