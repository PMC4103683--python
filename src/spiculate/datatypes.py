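"""Core containers shared across the trace, kinetics, behavior and stats layers.

All times are seconds from recording start (t = 0 at the first frame) and all
intervals are half-open ``[start, end)``.  Fluorescence values are mean ROI
gray levels (arbitrary camera units); ``dff_percent`` is percent change of the
green:red ratio relative to its pre-insertion baseline F0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "EVENT_NAMES",
    "DualChannelTrace",
    "EventLog",
    "BleachModel",
    "DffTrace",
    "KineticFeatures",
    "MatingTrial",
    "ContingencyTable2x2",
]

#: Behavioral events scored from the mating recordings.
EVENT_NAMES = frozenset(
    {
        "placed",
        "commence",
        "vulva_contact_start",
        "vulva_contact_end",
        "vulva_pass",
        "insertion",
        "valve_open",
        "sperm_initiation",
        "sperm_release_start",
        "sperm_release_end",
        "retraction",
        "ectopic_ejaculation",
        "ectopic_protraction",
    }
)


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class DualChannelTrace:
    """Raw (or background-subtracted) dual-channel ROI mean time series.

    ``green`` is the Ca2+-sensitive G-CaMP channel, ``red`` the
    Ca2+-insensitive mDsRed reference.  ``green_bg``/``red_bg`` are matched
    background ROIs placed on the bacterial lawn; they are ``None`` once the
    background has been subtracted.
    """

    time_s: np.ndarray
    green: np.ndarray
    red: np.ndarray
    green_bg: Optional[np.ndarray] = None
    red_bg: Optional[np.ndarray] = None

    def __post_init__(self):
        object.__setattr__(self, "time_s", _as_array(self.time_s, "time_s"))
        object.__setattr__(self, "green", _as_array(self.green, "green"))
        object.__setattr__(self, "red", _as_array(self.red, "red"))
        n = self.time_s.size
        if n < 3:
            raise ValueError("trace must contain at least 3 samples")
        for name in ("green", "red"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != time length {n}")
        for name in ("green_bg", "red_bg"):
            val = getattr(self, name)
            if val is not None:
                arr = _as_array(val, name)
                if arr.size != n:
                    raise ValueError(f"{name} length {arr.size} != time length {n}")
                object.__setattr__(self, name, arr)
        if np.any(np.diff(self.time_s) <= 0):
            bad = int(np.argmax(np.diff(self.time_s) <= 0)) + 1
            raise ValueError(f"time_s must be strictly increasing (violated at sample {bad})")
        if np.any(self.green < 0) or np.any(self.red < 0):
            raise ValueError("fluorescence values must be non-negative")

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def has_background(self) -> bool:
        return self.green_bg is not None and self.red_bg is not None

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def replace(self, **kwargs) -> "DualChannelTrace":
        return replace(self, **kwargs)


class EventLog(dict):
    """Mapping from event name to a sorted list of event times in seconds.

    Behaves as a plain dict; values are normalised to sorted float lists on
    construction.  Unknown event names are rejected so that typos in scored
    logs surface immediately.
    """

    def __init__(self, events: Optional[dict] = None, **kwargs):
        super().__init__()
        merged = dict(events or {})
        merged.update(kwargs)
        for name, times in merged.items():
            self[name] = times

    def __setitem__(self, name, times):
        if name not in EVENT_NAMES:
            raise KeyError(
                f"unknown event name {name!r}; valid names: {sorted(EVENT_NAMES)}"
            )
        if np.isscalar(times):
            times = [times]
        super().__setitem__(name, sorted(float(t) for t in times))

    def first(self, name: str) -> Optional[float]:
        """Time of the first occurrence of *name*, or ``None``."""
        times = self.get(name)
        return times[0] if times else None

    def to_json_dict(self) -> dict:
        return {k: list(v) for k, v in self.items()}


@dataclass(frozen=True)
class BleachModel:
    """Mono-exponential photobleaching model ``A * exp(-t / tau) + offset``.

    ``tau_s`` is ``nan`` for degenerate (constant) input, in which case the
    model is the constant ``offset``.  ``rss`` is the residual sum of squares
    of the least-squares fit.
    """

    amplitude: float
    tau_s: float
    offset: float
    rss: float = 0.0

    def __post_init__(self):
        if not math.isnan(self.tau_s) and self.tau_s <= 0:
            raise ValueError("tau_s must be positive (or nan for a constant model)")
        if self.amplitude + self.offset <= 0:
            raise ValueError("amplitude + offset must be positive")

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.tau_s)

    def predict(self, time_s) -> np.ndarray:
        t = np.asarray(time_s, dtype=float)
        if self.degenerate or self.amplitude == 0:
            return np.full_like(t, self.offset, dtype=float)
        return self.amplitude * np.exp(-t / self.tau_s) + self.offset

    def __call__(self, time_s) -> np.ndarray:
        return self.predict(time_s)


@dataclass(frozen=True)
class DffTrace:
    """Baseline-normalised %ΔF/F0 series with its event log.

    ``f0`` is the baseline green:red ratio (or baseline green level for
    single-channel traces) that the trace is normalised against.
    """

    time_s: np.ndarray
    dff_percent: np.ndarray
    f0: float
    events: EventLog = field(default_factory=EventLog)

    def __post_init__(self):
        object.__setattr__(self, "time_s", _as_array(self.time_s, "time_s"))
        object.__setattr__(self, "dff_percent", _as_array(self.dff_percent, "dff_percent"))
        if self.time_s.size != self.dff_percent.size:
            raise ValueError("time_s and dff_percent must have equal length")
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if not isinstance(self.events, EventLog):
            object.__setattr__(self, "events", EventLog(self.events))

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def dt_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))

    def slice(self, t_start: float, t_end: float) -> "DffTrace":
        """Samples with ``t_start <= t < t_end`` (half-open)."""
        mask = (self.time_s >= t_start) & (self.time_s < t_end)
        if not mask.any():
            raise ValueError(f"no samples in window [{t_start}, {t_end})")
        return DffTrace(self.time_s[mask], self.dff_percent[mask], self.f0, self.events)


@dataclass
class KineticFeatures:
    """Event-aligned transient statistics for one bout.

    Optional fields are ``None`` when the corresponding feature is undefined
    (no detectable transient, no second rise).  ``flags`` collects free-text
    quality notes (e.g. truncated post-peak window).
    """

    onset_s: Optional[float] = None
    peak_time_s: Optional[float] = None
    insertion_to_peak_s: Optional[float] = None
    peak_dff: Optional[float] = None
    rise_slope: Optional[float] = None
    second_rise_onset_s: Optional[float] = None
    second_peak_time_s: Optional[float] = None
    second_rise_slope: Optional[float] = None
    post_peak_15s_slope: Optional[float] = None
    flags: list = field(default_factory=list)

    NUMERIC_FIELDS = (
        "onset_s",
        "peak_time_s",
        "insertion_to_peak_s",
        "peak_dff",
        "rise_slope",
        "second_rise_onset_s",
        "second_peak_time_s",
        "second_rise_slope",
        "post_peak_15s_slope",
    )

    def __post_init__(self):
        if (
            self.onset_s is not None
            and self.peak_time_s is not None
            and self.onset_s > self.peak_time_s
        ):
            raise ValueError("onset_s must not exceed peak_time_s")
        if self.insertion_to_peak_s is not None and self.insertion_to_peak_s < 0:
            raise ValueError("insertion_to_peak_s must be non-negative")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.NUMERIC_FIELDS}
        d["flags"] = ";".join(self.flags)
        return d


@dataclass
class MatingTrial:
    """One male's scored behavioral record for a mating trial.

    ``insertions`` are ``(insert_s, retract_s)`` pairs; an unfinished final
    insertion may use ``nan`` for its retraction time.  ``progeny`` is a list
    of cross-progeny counts per insertion (``None`` if not scored).
    """

    male_id: str
    group: str = ""
    placed_s: float = 0.0
    commence_s: list = field(default_factory=list)
    vulva_contacts: list = field(default_factory=list)
    vulva_passes: int = 0
    insertions: list = field(default_factory=list)
    sperm_release: Optional[tuple] = None
    outcome: str = "neither"
    ectopic_protraction: bool = False
    progeny: Optional[list] = None

    OUTCOMES = (
        "uterine_ejaculation",
        "insert_no_ejaculation",
        "ectopic_ejaculation",
        "neither",
    )

    def __post_init__(self):
        if self.outcome not in self.OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; valid: {self.OUTCOMES}")
        self.commence_s = sorted(float(t) for t in self.commence_s)
        ins = [(float(a), float(b)) for a, b in self.insertions]
        for a, b in ins:
            if not math.isnan(b) and b < a:
                raise ValueError("insertion retract time precedes insert time")
        for (a0, b0), (a1, _) in zip(ins, ins[1:]):
            if math.isnan(b0) or a1 < b0:
                raise ValueError("insertion intervals must alternate in time")
        self.insertions = ins
        self.vulva_contacts = [(float(a), float(b)) for a, b in self.vulva_contacts]
        for a, b in self.vulva_contacts:
            if b < a:
                raise ValueError("vulva contact end precedes start")
        if self.sperm_release is not None:
            a, b = self.sperm_release
            if b < a:
                raise ValueError("sperm release end precedes start")
            self.sperm_release = (float(a), float(b))
        # outcome / evidence consistency
        if self.outcome == "uterine_ejaculation" and (
            not self.insertions or self.sperm_release is None
        ):
            raise ValueError("uterine_ejaculation requires an insertion and a release interval")
        if self.outcome == "insert_no_ejaculation" and not self.insertions:
            raise ValueError("insert_no_ejaculation requires at least one insertion")
        if self.outcome == "ectopic_ejaculation" and self.insertions:
            raise ValueError("ectopic_ejaculation is scored for males that did not insert")
        if self.outcome == "neither" and (self.insertions or self.sperm_release):
            raise ValueError("outcome 'neither' is inconsistent with recorded insertions/release")

    @property
    def inserted(self) -> bool:
        return bool(self.insertions)

    @property
    def first_insert_s(self) -> Optional[float]:
        return self.insertions[0][0] if self.insertions else None


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 success/failure table; rows are groups, columns success/failure."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple = ("group1", "group2")
    col_labels: tuple = ("success", "failure")

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
            object.__setattr__(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a, self.c, self.b, self.d, self.col_labels, self.row_labels
        )
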