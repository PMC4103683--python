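"""Ground-truth kinetic presets for the synthetic bout generator.

Each preset encodes the published cohort kinetics of one cell class recorded
during *C. elegans* male intromission: mean and SD of the insertion-to-peak
latency and of the initial rise slope, plus the waveform, bleaching and noise
parameters the generator needs.  The peak amplitude (in %ΔF/F0) is the
product ``rise_slope * (time_to_peak_s - onset_delay_s)`` so that a straight
rise at the preset slope reaches the peak exactly at the preset latency.

Preset kinetics (cohort mean ± SD):

========================  =======================  =========================
preset                    insertion→peak (s)        initial rise slope (%/s)
========================  =======================  =========================
``spc``                   1.3 ± 0.52               45 ± 13
``valve``                 1.8 ± 0.79               60 ± 14
``spv_spd``               4.0 ± 1.0                21 ± 14
``pca``                   6.3 ± 0.56               15 ± 2.9
``socket``                1.7 ± 0.36               94 ± 18
``muscles_monophasic``    1.3 ± 1.7                155 ± 82
``muscles_biphasic``      first peak as above;     second rise 46 ± 19,
                          second peak 11 ± 3.9 s
``spc_control``           1.2 ± 0.30               60 ± 26
``spc_ablated``           2.2 ± 0.74               29 ± 12
``pcb_weak``              minor, fast-dissipating transient
``ray_flat``              no transient (zero amplitude)
``valve_tips_cut``        valve kinetics with a protracted, more gradual
                          post-peak decline (spicule-tips-cut phenotype)
========================  =======================  =========================

The ``valve`` preset additionally emits a ``valve_open`` event 6.9 ± 1.5 s
after insertion (the measured insertion-to-valve-opening latency), and the
muscle presets emit sperm-release events so that oscillation onset can be
tied to the end of transfer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = ["KineticPreset", "SecondRise", "Oscillation", "PRESET_NAMES", "make_preset"]


@dataclass(frozen=True)
class SecondRise:
    """Delayed second transient (biphasic traces), relative to insertion."""

    onset_s: float
    time_to_peak_s: float
    amplitude: float
    time_to_peak_sd_s: float = 0.0
    slope_sd: float = 0.0

    def __post_init__(self):
        if not self.time_to_peak_s > self.onset_s:
            raise ValueError("second rise must peak after its onset")

    @property
    def slope(self) -> float:
        return self.amplitude / (self.time_to_peak_s - self.onset_s)


@dataclass(frozen=True)
class Oscillation:
    """Damped post-event oscillation (sex-muscle transfer dynamics)."""

    period_s: float
    amplitude: float
    start_event: str = "sperm_release_end"
    damping_tau_s: float = 10.0

    def __post_init__(self):
        if self.period_s <= 0 or self.amplitude < 0:
            raise ValueError("oscillation period must be positive, amplitude non-negative")


@dataclass(frozen=True)
class KineticPreset:
    """Complete ground-truth parameterisation of one synthetic bout class.

    Waveform: linear (or sigmoidal) rise from ``onset_delay_s`` after
    insertion to ``peak_amplitude`` %ΔF/F0 at ``time_to_peak_s`` after
    insertion; the decline is the sum of a fast off-relaxation toward
    ``sustained_fraction`` of the peak (time constant ``off_tau_s``; by
    default ``(1 - sustained_fraction) * rise duration``, which makes the
    transient leave its apex at the same initial rate it rose, so the apex
    is locally symmetric) and a slow linear return to baseline at
    ``decay_rate`` %ΔF/F0 per second.
    The red reference bleaches mono-exponentially with time constant
    ``red_bleach_tau_s`` toward ``red_bleach_floor`` of its initial level.
    Noise is additive Gaussian per sample and channel, ``noise_sd`` percent
    of the channel baseline.
    """

    name: str
    f0_green: float = 200.0
    f0_red: float = 200.0
    peak_amplitude: float = 50.0
    onset_delay_s: float = 0.0
    time_to_peak_s: float = 1.5
    time_to_peak_sd_s: float = 0.0
    rise_slope_sd: float = 0.0
    rise_shape: str = "linear"
    decay_rate: float = 3.0
    sustained_fraction: float = 0.5
    off_tau_s: Optional[float] = None
    second_rise: Optional[SecondRise] = None
    oscillation: Optional[Oscillation] = None
    red_bleach_tau_s: float = 60.0
    red_bleach_floor: float = 0.3
    noise_sd: float = 3.0
    background_level: float = 50.0
    event_delays: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.time_to_peak_s > self.onset_delay_s >= 0):
            raise ValueError("require time_to_peak_s > onset_delay_s >= 0")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.red_bleach_tau_s <= 0:
            raise ValueError("red_bleach_tau_s must be positive")
        if not (0 <= self.red_bleach_floor < 1):
            raise ValueError("red_bleach_floor must be in [0, 1)")
        if self.rise_shape not in ("linear", "sigmoidal"):
            raise ValueError("rise_shape must be 'linear' or 'sigmoidal'")
        if not (0 <= self.sustained_fraction <= 1):
            raise ValueError("sustained_fraction must be in [0, 1]")
        if self.second_rise is not None and not (
            self.second_rise.onset_s > self.time_to_peak_s
        ):
            raise ValueError("second rise must start after the first peak")

    @property
    def rise_slope(self) -> float:
        """Mean initial rise slope implied by amplitude and rise duration (%/s)."""
        return self.peak_amplitude / (self.time_to_peak_s - self.onset_delay_s)

    def with_(self, **kwargs) -> "KineticPreset":
        return replace(self, **kwargs)


def _from_slope(name: str, ttp: float, ttp_sd: float, slope: float, slope_sd: float,
                **kwargs) -> KineticPreset:
    return KineticPreset(
        name=name,
        time_to_peak_s=ttp,
        time_to_peak_sd_s=ttp_sd,
        peak_amplitude=slope * ttp,
        rise_slope_sd=slope_sd,
        **kwargs,
    )


_MUSCLE_EVENTS = {
    "sperm_release_start": (15.0, 2.0),
    "sperm_release_end": (32.0, 4.0),
}

_PRESETS = {
    "spc": _from_slope("spc", 1.3, 0.52, 45.0, 13.0),
    "valve": _from_slope(
        "valve", 1.8, 0.79, 60.0, 14.0,
        sustained_fraction=0.7, decay_rate=2.0,
        event_delays={"valve_open": (6.9, 1.5)},
    ),
    "spv_spd": _from_slope("spv_spd", 4.0, 1.0, 21.0, 14.0),
    "pca": _from_slope("pca", 6.3, 0.56, 15.0, 2.9, sustained_fraction=0.6),
    "socket": _from_slope("socket", 1.7, 0.36, 94.0, 18.0),
    "muscles_monophasic": _from_slope(
        "muscles_monophasic", 1.3, 1.7, 155.0, 82.0,
        event_delays=dict(_MUSCLE_EVENTS),
    ),
    "muscles_biphasic": _from_slope(
        "muscles_biphasic", 1.3, 1.7, 155.0, 82.0,
        second_rise=SecondRise(
            onset_s=8.5, time_to_peak_s=11.0, amplitude=46.0 * 2.5,
            time_to_peak_sd_s=3.9, slope_sd=19.0,
        ),
        oscillation=Oscillation(period_s=2.0, amplitude=10.0),
        event_delays=dict(_MUSCLE_EVENTS),
    ),
    "spc_control": _from_slope("spc_control", 1.2, 0.30, 60.0, 26.0),
    "spc_ablated": _from_slope("spc_ablated", 2.2, 0.74, 29.0, 12.0),
    "pcb_weak": _from_slope("pcb_weak", 1.5, 0.5, 10.0, 4.0, sustained_fraction=0.1),
    "ray_flat": KineticPreset(
        name="ray_flat", peak_amplitude=0.0, time_to_peak_s=1.0,
    ),
    "valve_tips_cut": _from_slope(
        "valve_tips_cut", 1.8, 0.79, 60.0, 14.0,
        sustained_fraction=0.9, decay_rate=0.8,
    ),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def make_preset(name: str) -> KineticPreset:
    """Return the documented kinetic preset called *name*.

    Raises ``KeyError`` naming the valid presets for an unknown name.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None
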