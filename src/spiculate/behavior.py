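"""Behavioral scoring of mating trials.

Metrics follow the mating-ethogram conventions used for male *C. elegans*
cohort comparisons: the composite sperm-transfer ranking, the refractory
period (1st to 2nd spicule insertion), mating-drive commencement times,
time-at-vulva and vulva passes, insertion-time metrics around the 2nd
insert, the >=10 s sustained-transfer criterion, the short/long refractory
binning, and per-insertion mating potency.

All interval metrics use half-open ``[start, end)`` intervals and are
invariant under a global time shift of the trial.  Undefined metrics are
``None``, never zero.
"""

from __future__ import annotations

import math
import warnings
from typing import List, Optional

from .datatypes import MatingTrial

__all__ = [
    "rank_sperm_transfer",
    "refractory_period",
    "drive_metrics",
    "vulva_metrics",
    "insertion_metrics",
    "classify_sustained_transfer",
    "bin_refractory",
    "potency",
]

#: Observation cap for the sperm-transfer ranking (5 min).
RANK_CAP_S = 300.0
#: Short/long refractory split: [180 s, 540 s) vs [540 s, 1800 s].
REFRACTORY_SPLIT_S = 540.0
REFRACTORY_RANGE_S = (180.0, 1800.0)
#: Sustained (wild-type) sperm transfer threshold, seconds.
SUSTAINED_TRANSFER_S = 10.0

_OUTCOME_CATEGORY = {
    "uterine_ejaculation": 0,
    "insert_no_ejaculation": 1,
    "ectopic_ejaculation": 2,
    "neither": 3,
}


def rank_sperm_transfer(trial: MatingTrial, cap_s: float = RANK_CAP_S) -> float:
    """Composite sperm-transfer ranking in [0, 4].

    Outcome category (0 = ejaculated into the uterus, 1 = inserted without
    ejaculating, 2 = ejaculated without inserting, 3 = neither) plus the
    time-to-insert divided by the cap.  Males that did not insert within the
    cap contribute the full ``cap_s / cap_s = 1`` time term (censored at the
    5-minute observation limit); lower scores are more successful males.
    """
    category = _OUTCOME_CATEGORY[trial.outcome]
    if trial.inserted:
        t_insert = trial.first_insert_s - trial.placed_s
        if t_insert < 0:
            raise ValueError("insertion precedes placement")
        time_term = min(t_insert, cap_s) / cap_s
    else:
        time_term = 1.0
    return category + time_term


def refractory_period(trial: MatingTrial) -> Optional[float]:
    """Seconds from 1st to 2nd spicule insertion; ``None`` if < 2 inserts."""
    if len(trial.insertions) < 2:
        return None
    return trial.insertions[1][0] - trial.insertions[0][0]


def drive_metrics(trial: MatingTrial) -> dict:
    """First and second commencement latencies.

    ``first_commencement_s``: placement to first backing along a mate.
    ``second_commencement_s``: first retraction to the next commencement.
    Missing events yield ``None``.
    """
    first = trial.commence_s[0] - trial.placed_s if trial.commence_s else None
    second = None
    if trial.insertions:
        retract = trial.insertions[0][1]
        if not math.isnan(retract):
            later = [c for c in trial.commence_s if c >= retract]
            if later:
                second = later[0] - retract
    return {"first_commencement_s": first, "second_commencement_s": second}


def vulva_metrics(trial: MatingTrial) -> dict:
    """Total pre-insertion time at the vulva and the vulva-pass count.

    Contacts are clipped at the first insertion (the stay during which the
    male inserted counts only up to insertion, flagged via truncation).
    Overlapping contact intervals are an error.
    """
    contacts = sorted(trial.vulva_contacts)
    for (a0, b0), (a1, _) in zip(contacts, contacts[1:]):
        if a1 < b0:
            raise ValueError(f"overlapping vulva contacts: [{a0}, {b0}) and starting {a1}")
    cutoff = trial.first_insert_s if trial.inserted else math.inf
    total = 0.0
    for start, end in contacts:
        if start >= cutoff:
            continue
        total += min(end, cutoff) - start
    return {"total_time_at_vulva_s": total, "passes": trial.vulva_passes}


def insertion_metrics(trial: MatingTrial) -> dict:
    """Insertion-duration metrics around the 1st and 2nd inserts.

    ``first_total_s``: duration of the first insertion.
    ``second_window_total_s``: summed inserted time clipped to the 30 s
    following the 2nd insert (operated males insert/retract repeatedly).
    ``inserts_in_60s`` / ``retracts_in_60s``: event counts in the 60 s after
    the 2nd insert (the 2nd insert itself is not counted).
    """
    if not trial.insertions:
        raise ValueError("trial has no insertions")
    i1, r1 = trial.insertions[0]
    first_total = (r1 - i1) if not math.isnan(r1) else None
    out = {
        "first_total_s": first_total,
        "second_window_total_s": None,
        "inserts_in_60s": None,
        "retracts_in_60s": None,
    }
    if len(trial.insertions) >= 2:
        i2 = trial.insertions[1][0]
        w30 = (i2, i2 + 30.0)
        total = 0.0
        for a, b in trial.insertions[1:]:
            end = b if not math.isnan(b) else w30[1]
            total += max(0.0, min(end, w30[1]) - max(a, w30[0]))
        out["second_window_total_s"] = total
        w60 = (i2, i2 + 60.0)
        out["inserts_in_60s"] = sum(
            1 for a, _ in trial.insertions if w60[0] < a <= w60[1]
        )
        out["retracts_in_60s"] = sum(
            1
            for _, b in trial.insertions
            if not math.isnan(b) and w60[0] < b <= w60[1]
        )
    return out


def classify_sustained_transfer(trial: MatingTrial) -> bool:
    """True iff the male transferred sperm for >= 10 s (wild-type transfer)."""
    if trial.sperm_release is None:
        return False
    start, end = trial.sperm_release
    return (end - start) >= SUSTAINED_TRANSFER_S


def bin_refractory(trials: List[MatingTrial]) -> dict:
    """Partition trials into short [180, 540) and long [540, 1800] refractory
    groups; trials outside that range or without a defined refractory period
    are reported separately."""
    short, long_, out_of_range, undefined = [], [], [], []
    lo, hi = REFRACTORY_RANGE_S
    for trial in trials:
        rp = refractory_period(trial)
        if rp is None:
            undefined.append(trial)
        elif rp < lo or rp > hi:
            out_of_range.append(trial)
        elif rp < REFRACTORY_SPLIT_S:
            short.append(trial)
        else:
            long_.append(trial)
    return {
        "short": short,
        "long": long_,
        "out_of_range": out_of_range,
        "undefined": undefined,
    }


def potency(trials: List[MatingTrial]) -> dict:
    """Fraction of males siring progeny, per insertion index (0-based).

    Trials without progeny records are excluded with a warning; no scorable
    trial at all is an error.
    """
    scored = [t for t in trials if t.progeny is not None]
    skipped = len(trials) - len(scored)
    if skipped:
        warnings.warn(f"excluded {skipped} trial(s) without progeny records", stacklevel=2)
    if not scored:
        raise ValueError("no trials with progeny records")
    n_inserts = max(len(t.progeny) for t in scored)
    fractions = {}
    for idx in range(n_inserts):
        counts = [t.progeny[idx] for t in scored if len(t.progeny) > idx]
        if counts:
            fractions[idx] = sum(1 for c in counts if c > 0) / len(counts)
    return fractions
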