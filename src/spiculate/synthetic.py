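"""Synthetic dual-channel bout, trial-population and contingency generators.

Everything here is a pure function of (parameters, seed): the same inputs
always produce bit-identical output.  Cohort generators derive per-bout seeds
from the master seed with ``numpy.random.SeedSequence(seed, spawn_key=...)``,
so individual bouts can be regenerated independently and the drawn
ground-truth kinetics can be recovered exactly via
:func:`cohort_ground_truth` without re-simulating the traces.

Per-bout kinetic variability uses moment-matched lognormal draws (latencies,
slopes and durations are positive, right-skewed quantities), with the preset
mean and SD as the lognormal mean and SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .datatypes import ContingencyTable2x2, DualChannelTrace, EventLog, MatingTrial
from .presets import KineticPreset, Oscillation, SecondRise, make_preset

__all__ = [
    "simulate_bout",
    "simulate_cohort",
    "cohort_ground_truth",
    "simulate_contingency",
    "TrialSpec",
    "simulate_trials",
    "trials_from_frame",
]


# ---------------------------------------------------------------------------
# waveform


def _rise_fraction(x: np.ndarray, shape: str) -> np.ndarray:
    """Normalised rise profile on x in [0, 1]."""
    if shape == "linear":
        return x
    # logistic rescaled to pass through (0, 0) and (1, 1)
    g = 10.0
    lo = 1.0 / (1.0 + math.exp(g / 2.0))
    hi = 1.0 / (1.0 + math.exp(-g / 2.0))
    return (1.0 / (1.0 + np.exp(-g * (x - 0.5))) - lo) / (hi - lo)


def _transient_component(
    t: np.ndarray,
    t_on: float,
    t_pk: float,
    amplitude: float,
    shape: str,
    sustained: float,
    off_tau: Optional[float],
    decay_rate: float,
) -> np.ndarray:
    """One rise/decay transient in %ΔF/F0 units.

    Rise from ``t_on`` to ``amplitude`` at ``t_pk``; afterwards a fast
    off-relaxation toward ``sustained * amplitude`` plus a slow linear return
    to baseline, clipped at zero.  When ``off_tau`` is ``None`` it defaults
    to ``(1 - sustained) * (t_pk - t_on)``, which makes the initial
    post-peak relaxation rate equal the rise rate (locally symmetric apex).
    """
    out = np.zeros_like(t)
    if amplitude == 0:
        return out
    if off_tau is None:
        off_tau = max((1.0 - sustained) * (t_pk - t_on), 1e-6)
    rising = (t >= t_on) & (t <= t_pk)
    out[rising] = amplitude * _rise_fraction((t[rising] - t_on) / (t_pk - t_on), shape)
    after = t > t_pk
    dt_after = t[after] - t_pk
    level = amplitude * (sustained + (1.0 - sustained) * np.exp(-dt_after / off_tau))
    out[after] = np.clip(level - decay_rate * dt_after, 0.0, None)
    return out


def transient_waveform(
    preset: KineticPreset, t: np.ndarray, insertion_time_s: float,
    events: Optional[EventLog] = None,
) -> np.ndarray:
    """Noise-free %ΔF/F0 waveform of *preset* on time base *t*."""
    tr = _transient_component(
        t,
        insertion_time_s + preset.onset_delay_s,
        insertion_time_s + preset.time_to_peak_s,
        preset.peak_amplitude,
        preset.rise_shape,
        preset.sustained_fraction,
        preset.off_tau_s,
        preset.decay_rate,
    )
    sr = preset.second_rise
    if sr is not None:
        tr += _transient_component(
            t,
            insertion_time_s + sr.onset_s,
            insertion_time_s + sr.time_to_peak_s,
            sr.amplitude,
            preset.rise_shape,
            preset.sustained_fraction,
            preset.off_tau_s,
            preset.decay_rate,
        )
    osc = preset.oscillation
    if osc is not None and events is not None:
        start = events.first(osc.start_event)
        if start is not None:
            dt_after = t - start
            mask = dt_after > 0
            tr[mask] += (
                osc.amplitude
                * np.sin(2.0 * np.pi * dt_after[mask] / osc.period_s)
                * np.exp(-dt_after[mask] / osc.damping_tau_s)
            )
    return tr


# ---------------------------------------------------------------------------
# bouts


def simulate_bout(
    preset: KineticPreset,
    insertion_time_s: float = 5.0,
    duration_s: float = 45.0,
    dt_s: float = 0.05,
    seed: int = 0,
) -> Tuple[DualChannelTrace, EventLog]:
    """Simulate one dual-channel recording of a mating bout.

    Green channel: ``background + f0_green * (1 + noise + transient/100)``.
    Red channel: ``background + f0_red * (floor + (1-floor) * exp(-t/tau))
    * (1 + noise)``.  The event log always contains ``insertion``; presets
    may add further events (``valve_open``, sperm-release marks) at their
    documented latencies.  Deterministic under ``seed``.
    """
    if isinstance(preset, str):
        preset = make_preset(preset)
    if not dt_s > 0:
        raise ValueError("dt_s must be positive")
    if not dt_s < duration_s:
        raise ValueError("dt_s must be smaller than duration_s")
    if not insertion_time_s + preset.time_to_peak_s < duration_s:
        raise ValueError(
            "duration too short: transient peak at "
            f"{insertion_time_s + preset.time_to_peak_s:.2f} s exceeds "
            f"duration {duration_s:.2f} s"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt_s)

    events = EventLog({"insertion": [insertion_time_s]})
    for name, (mean, sd) in sorted(preset.event_delays.items()):
        delay = rng.normal(mean, sd) if sd > 0 else mean
        delay = max(delay, dt_s)
        t_event = insertion_time_s + delay
        if t_event < duration_s:
            events[name] = [t_event]

    tr = transient_waveform(preset, t, insertion_time_s, events)
    sigma = preset.noise_sd / 100.0
    noise_g = rng.normal(0.0, sigma, t.size) if sigma > 0 else 0.0
    noise_r = rng.normal(0.0, sigma, t.size) if sigma > 0 else 0.0
    green = preset.background_level + preset.f0_green * (1.0 + noise_g + tr / 100.0)
    bleach = preset.red_bleach_floor + (1.0 - preset.red_bleach_floor) * np.exp(
        -t / preset.red_bleach_tau_s
    )
    red = preset.background_level + preset.f0_red * bleach * (1.0 + noise_r)
    green_bg = np.full(t.size, preset.background_level)
    red_bg = np.full(t.size, preset.background_level)
    trace = DualChannelTrace(
        t, np.clip(green, 0, None), np.clip(red, 0, None), green_bg, red_bg
    )
    return trace, events


def _lognormal_draw(rng: np.random.Generator, mean: float, sd: float, n: int = 1):
    """Lognormal samples with the given arithmetic mean and SD."""
    if mean <= 0:
        return np.zeros(n)
    if sd <= 0:
        return np.full(n, mean)
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    # clip the far upper tail (< 1% mass): unbounded lognormal draws produce
    # unphysical kinetics (e.g. multi-thousand-percent transients)
    return np.minimum(rng.lognormal(mu, math.sqrt(s2), n), mean + 4.0 * sd)


def _bout_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(1 + index,))
    return int(ss.generate_state(1, np.uint32)[0])


def cohort_ground_truth(
    preset: KineticPreset,
    n: int,
    seed: int = 0,
    insertion_window_s: Tuple[float, float] = (4.0, 6.0),
    duration_s: float = 45.0,
) -> pd.DataFrame:
    """Per-bout ground-truth parameters drawn by :func:`simulate_cohort`.

    Pure function of (preset, n, seed, window): calling it does not simulate
    any traces, it replays the deterministic parameter draws.
    """
    if isinstance(preset, str):
        preset = make_preset(preset)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    lo, hi = insertion_window_s
    rows = []
    rise_mean = preset.time_to_peak_s - preset.onset_delay_s
    for i in range(n):
        insertion = float(rng.uniform(lo, hi))
        rise_dur = float(_lognormal_draw(rng, rise_mean, preset.time_to_peak_sd_s)[0])
        slope = float(_lognormal_draw(rng, preset.rise_slope, preset.rise_slope_sd)[0])
        # keep the full transient inside the recording
        max_rise = duration_s - insertion - 10.0
        rise_dur = min(max(rise_dur, 2e-2), max_rise)
        ttp = preset.onset_delay_s + rise_dur
        row = {
            "bout": i,
            "seed": _bout_seed(seed, i),
            "insertion_s": insertion,
            "time_to_peak_s": ttp,
            "rise_slope": slope,
            "peak_amplitude": slope * rise_dur,
        }
        sr = preset.second_rise
        if sr is not None:
            rise2 = sr.time_to_peak_s - sr.onset_s
            ttp2 = float(_lognormal_draw(rng, sr.time_to_peak_s, sr.time_to_peak_sd_s)[0])
            ttp2 = max(ttp2, ttp + 0.7)
            onset2 = max(ttp2 - rise2, ttp + 0.2)
            slope2 = float(_lognormal_draw(rng, sr.slope, sr.slope_sd)[0])
            row.update(
                {
                    "second_onset_s": onset2,
                    "second_peak_time_s": ttp2,
                    "second_rise_slope": slope2,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort(
    preset: KineticPreset,
    n: int,
    dt_s: float = 0.05,
    duration_s: float = 45.0,
    seed: int = 0,
    insertion_window_s: Tuple[float, float] = (4.0, 6.0),
) -> List[Tuple[DualChannelTrace, EventLog]]:
    """Simulate *n* independent bouts with per-bout kinetic variability.

    Insertion times are jittered uniformly within ``insertion_window_s``;
    per-bout latency and rise slope are lognormal draws around the preset
    mean/SD (peak amplitude follows as slope x rise duration).  Bout *i* uses
    the derived seed ``SeedSequence(seed, spawn_key=(1+i,))``, so the cohort
    is reproducible bout-by-bout; :func:`cohort_ground_truth` replays the
    parameter draws.
    """
    if isinstance(preset, str):
        preset = make_preset(preset)
    truth = cohort_ground_truth(preset, n, seed, insertion_window_s, duration_s)
    bouts = []
    for row in truth.itertuples():
        rise_dur = row.time_to_peak_s - preset.onset_delay_s
        overrides = dict(
            time_to_peak_s=row.time_to_peak_s,
            peak_amplitude=row.rise_slope * rise_dur,
            time_to_peak_sd_s=0.0,
            rise_slope_sd=0.0,
        )
        if preset.second_rise is not None:
            overrides["second_rise"] = SecondRise(
                onset_s=row.second_onset_s,
                time_to_peak_s=row.second_peak_time_s,
                amplitude=row.second_rise_slope
                * (row.second_peak_time_s - row.second_onset_s),
            )
        bout_preset = preset.with_(**overrides)
        bouts.append(
            simulate_bout(
                bout_preset,
                insertion_time_s=row.insertion_s,
                duration_s=duration_s,
                dt_s=dt_s,
                seed=int(row.seed),
            )
        )
    return bouts


# ---------------------------------------------------------------------------
# contingency outcomes


def simulate_contingency(
    n1: int, p1: float, n2: int, p2: float, seed: int = 0,
    labels: Tuple[str, str] = ("group1", "group2"),
) -> ContingencyTable2x2:
    """Binomial success/failure draws for two groups as a 2x2 table."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s1 = int(rng.binomial(n1, p1))
    s2 = int(rng.binomial(n2, p2))
    return ContingencyTable2x2(s1, n1 - s1, s2, n2 - s2, row_labels=labels)


# ---------------------------------------------------------------------------
# trial populations


@dataclass(frozen=True)
class TrialSpec:
    """Parameter shell for simulating a cohort of scored mating trials.

    Distributions are ``(mean_s, sd_s)`` of moment-matched lognormals.
    Defaults emulate intact 1-day-old virgin males: commencement within
    ~34 s, insertion within ~2 min of commencing, a ~12 min (SD ~6.5 min)
    refractory period, first-insertion duration ~94 s and ~17 s of sperm
    transfer.
    """

    group_label: str = "control"
    n_males: int = 20
    p_insert: float = 0.9
    p_valve_open: float = 0.92
    p_release: float = 0.75
    refractory_distribution: Tuple[float, float] = (720.0, 390.0)
    insert_latency_distribution: Tuple[float, float] = (100.0, 50.0)
    transfer_duration_distribution: Tuple[float, float] = (17.0, 5.0)
    commence_latency_distribution: Tuple[float, float] = (34.0, 20.0)
    insertion_duration_distribution: Tuple[float, float] = (94.0, 30.0)
    second_commence_distribution: Tuple[float, float] = (300.0, 150.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_males < 1:
            raise ValueError("n_males must be >= 1")
        for name in ("p_insert", "p_valve_open", "p_release"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "refractory_distribution",
            "insert_latency_distribution",
            "transfer_duration_distribution",
            "commence_latency_distribution",
            "insertion_duration_distribution",
            "second_commence_distribution",
        ):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name} requires mean > 0 and sd >= 0")


TRIAL_COLUMNS = [
    "male_id", "group", "placed_s", "commence_s", "vulva_contact_start_s",
    "vulva_contact_end_s", "vulva_passes", "insert_s", "retract_s",
    "release_start_s", "release_end_s", "outcome", "ectopic_protraction",
    "progeny",
]


def _join(values) -> str:
    return ";".join(f"{v:.3f}" if isinstance(v, float) else str(v) for v in values)


def simulate_trials(spec: TrialSpec) -> pd.DataFrame:
    """Simulate one scored :class:`MatingTrial` row per male.

    Outcome model: an inserting male opens the gonadal valve with probability
    ``p_valve_open`` and, given an open valve, releases sperm into the uterus
    with probability ``p_release`` (outcome ``uterine_ejaculation``), else
    ``insert_no_ejaculation``.  Non-inserters ejaculate ectopically with
    probability ``p_valve_open * p_release``, else ``neither``.  Second-mating
    siring success increases with the refractory period (sperm-reserve
    recovery), which is what the short/long refractory binning probes.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_males):
        male_id = f"{spec.group_label}_{i:03d}"
        placed = 0.0
        c1 = placed + float(_lognormal_draw(rng, *spec.commence_latency_distribution)[0])
        inserted = rng.random() < spec.p_insert
        commences = [c1]
        contacts_start, contacts_end = [], []
        inserts, retracts = [], []
        release = (math.nan, math.nan)
        progeny: list = []
        outcome = "neither"
        ectopic_protraction = bool(rng.random() < 0.1)
        passes = int(rng.poisson(2))
        if inserted:
            i1 = c1 + float(_lognormal_draw(rng, *spec.insert_latency_distribution)[0])
            # two vulva stays, the second ending at insertion
            stay1 = float(_lognormal_draw(rng, 12.0, 6.0)[0])
            stay2 = float(_lognormal_draw(rng, 8.0, 4.0)[0])
            start2 = i1 - stay2
            start1 = max(c1, start2 - stay1 - 5.0)
            end1 = min(start1 + stay1, start2 - 1.0)
            if end1 > start1:
                contacts_start = [start1, start2]
                contacts_end = [end1, i1]
            else:
                contacts_start = [start2]
                contacts_end = [i1]
            d1 = float(_lognormal_draw(rng, *spec.insertion_duration_distribution)[0])
            r1 = i1 + d1
            inserts, retracts = [i1], [r1]
            valve_open = rng.random() < spec.p_valve_open
            released = valve_open and rng.random() < spec.p_release
            if released:
                outcome = "uterine_ejaculation"
                dur = float(_lognormal_draw(rng, *spec.transfer_duration_distribution)[0])
                rel_start = i1 + 5.0
                release = (rel_start, rel_start + dur)
                progeny.append(int(rng.poisson(25)) if dur >= 10.0 else 0)
            else:
                outcome = "insert_no_ejaculation"
                progeny.append(0)
            # second mating attempt: the drawn refractory period sets the
            # 2nd insert; commencement is clamped to precede it
            refractory = float(_lognormal_draw(rng, *spec.refractory_distribution)[0])
            refractory = max(refractory, d1 + 2.0)
            i2 = i1 + refractory
            c2 = min(
                r1 + float(_lognormal_draw(rng, *spec.second_commence_distribution)[0]),
                i2 - 2.0,
            )
            commences.append(c2)
            d2 = float(_lognormal_draw(rng, 30.0, 15.0)[0])
            inserts.append(i2)
            retracts.append(i2 + d2)
            # sperm-reserve recovery: longer refractory -> better 2nd siring
            p2 = min(0.9, max(0.0, (i2 - i1) / 1800.0)) if released else 0.1
            progeny.append(int(rng.poisson(20)) if rng.random() < p2 else 0)
        else:
            if rng.random() < spec.p_valve_open * spec.p_release:
                outcome = "ectopic_ejaculation"
        rows.append(
            {
                "male_id": male_id,
                "group": spec.group_label,
                "placed_s": placed,
                "commence_s": _join(commences),
                "vulva_contact_start_s": _join(contacts_start),
                "vulva_contact_end_s": _join(contacts_end),
                "vulva_passes": passes,
                "insert_s": _join(inserts),
                "retract_s": _join(retracts),
                "release_start_s": release[0],
                "release_end_s": release[1],
                "outcome": outcome,
                "ectopic_protraction": ectopic_protraction,
                "progeny": _join(progeny),
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _split(cell) -> list:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    return [float(x) for x in str(cell).split(";")]


def trials_from_frame(frame: pd.DataFrame) -> List[MatingTrial]:
    """Convert a trial table (as produced by :func:`simulate_trials`) into
    :class:`MatingTrial` objects."""
    trials = []
    for row in frame.to_dict("records"):
        inserts = _split(row["insert_s"])
        retracts = _split(row["retract_s"])
        release = None
        if not math.isnan(float(row["release_start_s"])):
            release = (float(row["release_start_s"]), float(row["release_end_s"]))
        progeny = [int(p) for p in _split(row["progeny"])] or None
        trials.append(
            MatingTrial(
                male_id=str(row["male_id"]),
                group=str(row["group"]),
                placed_s=float(row["placed_s"]),
                commence_s=_split(row["commence_s"]),
                vulva_contacts=list(
                    zip(_split(row["vulva_contact_start_s"]), _split(row["vulva_contact_end_s"]))
                ),
                vulva_passes=int(row["vulva_passes"]),
                insertions=list(zip(inserts, retracts)),
                sperm_release=release,
                outcome=str(row["outcome"]),
                ectopic_protraction=bool(row["ectopic_protraction"]),
                progeny=progeny,
            )
        )
    return trials
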