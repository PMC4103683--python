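"""Raw dual-channel ROI series -> bleach-corrected %ΔF/F0 traces.

The correction chain mirrors standard ratiometric G-CaMP/mDsRed practice:
background subtraction per channel, a mono-exponential-plus-offset decay fit
to the red reference (mDsRed bleaches appreciably over a bout; G-CaMP does
not), division of the green signal by the bleach-corrected red, and percent
change relative to the baseline ratio F0 taken over a pre-insertion window.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import BleachModel, DffTrace, DualChannelTrace, EventLog

__all__ = [
    "subtract_background",
    "fit_bleach_decay",
    "correct_red",
    "ratiometric_dff",
    "single_channel_dff",
    "restrained_summary",
    "default_f0_window",
]

logger = logging.getLogger(__name__)

#: Length of the default pre-insertion F0 baseline window, seconds.
DEFAULT_F0_SPAN_S = 2.0


def subtract_background(trace: DualChannelTrace) -> DualChannelTrace:
    """Subtract the per-frame background ROI means from each channel.

    Negative results are clipped to zero (gray levels are non-negative); a
    warning is logged when more than 1% of samples clip.
    """
    if not trace.has_background:
        raise ValueError("trace has no background series to subtract")
    green = trace.green - trace.green_bg
    red = trace.red - trace.red_bg
    n_clip = int(np.sum(green < 0) + np.sum(red < 0))
    if n_clip > 0.01 * 2 * len(trace):
        logger.warning(
            "background subtraction clipped %d of %d samples to zero",
            n_clip, 2 * len(trace),
        )
    return DualChannelTrace(
        trace.time_s, np.clip(green, 0.0, None), np.clip(red, 0.0, None)
    )


def _exp_offset(t, amplitude, tau, offset):
    return amplitude * np.exp(-t / tau) + offset


def fit_bleach_decay(red: np.ndarray, time_s: np.ndarray) -> BleachModel:
    """Least-squares fit of ``red(t) = A * exp(-t/tau) + offset``.

    Degenerate (constant) input returns ``amplitude=0, offset=mean`` with
    ``tau_s = nan``.  Non-convergence raises ``RuntimeError`` carrying the
    initial guesses.
    """
    red = np.asarray(red, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if red.size != time_s.size:
        raise ValueError("red and time_s must have equal length")
    if red.size < 10:
        raise ValueError("need at least 10 samples to fit the bleach decay")
    if np.ptp(red) == 0:
        return BleachModel(0.0, float("nan"), float(red.mean()), 0.0)

    span = time_s[-1] - time_s[0]
    offset0 = float(red.min())
    amp0 = max(float(red[0] - offset0), 1e-6 * max(red.max(), 1.0))
    tau0 = span / 3.0
    p0 = (amp0, tau0, offset0)
    try:
        popt, _ = curve_fit(
            _exp_offset, time_s, red, p0=p0,
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, max_nfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"bleach decay fit did not converge (initial guesses: "
            f"amplitude={p0[0]:.4g}, tau_s={p0[1]:.4g}, offset={p0[2]:.4g})"
        ) from exc
    amplitude, tau, offset = (float(v) for v in popt)
    rss = float(np.sum((red - _exp_offset(time_s, *popt)) ** 2))
    if amplitude < 1e-12 * max(offset, 1.0):
        return BleachModel(0.0, float("nan"), float(red.mean()), rss)
    return BleachModel(amplitude, tau, offset, rss)


def correct_red(
    red: np.ndarray, model: BleachModel, time_s: Optional[np.ndarray] = None
) -> np.ndarray:
    """Remove the fitted bleach trend: ``corrected = red * model(0)/model(t)``.

    The correction is normalised to the model value at t=0 so that the
    early-recording baseline (where F0 is taken) is unbiased.  For input that
    follows the model exactly, the output is constant at ``model(0)``.
    """
    red = np.asarray(red, dtype=float)
    if time_s is None:
        raise ValueError("time_s is required to evaluate the bleach model")
    fitted = model.predict(time_s)
    if np.any(fitted <= 0):
        raise ValueError("bleach model predicts non-positive values; cannot correct")
    return red * (model.predict(0.0) / fitted)


def default_f0_window(
    time_s: np.ndarray, events: Optional[EventLog],
    span_s: float = DEFAULT_F0_SPAN_S,
) -> Tuple[float, float]:
    """Baseline window: the ``span_s`` seconds preceding the first insertion
    (or all samples before it, whichever is shorter).  Without an insertion
    event, the first ``span_s`` seconds of the recording."""
    t0 = float(time_s[0])
    insertion = events.first("insertion") if events else None
    if insertion is None:
        return (t0, t0 + span_s)
    return (max(t0, insertion - span_s), insertion)


def _window_mask(time_s: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    t_start, t_end = window
    mask = (time_s >= t_start) & (time_s < t_end)
    if not mask.any():
        raise ValueError(f"empty F0 window [{t_start}, {t_end})")
    if mask.sum() < 5:
        warnings.warn(
            f"F0 window [{t_start}, {t_end}) contains only {int(mask.sum())} samples",
            stacklevel=3,
        )
    return mask


def ratiometric_dff(
    trace: DualChannelTrace,
    model: BleachModel,
    f0_window: Optional[Tuple[float, float]] = None,
    events: Optional[EventLog] = None,
) -> DffTrace:
    """Percent change of the green : corrected-red ratio relative to F0.

    ``r(t) = green / corrected_red``; ``F0`` is the mean of ``r`` over the
    baseline window (default: the 2 s before the first insertion event);
    ``dff = 100 * (r - F0) / F0``.  The trace must already be
    background-subtracted.
    """
    events = events if events is not None else EventLog()
    corrected = correct_red(trace.red, model, trace.time_s)
    if np.any(corrected <= 0):
        raise ValueError("corrected red contains non-positive values")
    ratio = trace.green / corrected
    if f0_window is None:
        f0_window = default_f0_window(trace.time_s, events)
    mask = _window_mask(trace.time_s, f0_window)
    f0 = float(ratio[mask].mean())
    if not f0 > 0:
        raise ValueError("baseline ratio F0 must be positive")
    dff = 100.0 * (ratio - f0) / f0
    return DffTrace(trace.time_s, dff, f0, events)


def single_channel_dff(
    green: np.ndarray,
    time_s: np.ndarray,
    f0_window: Optional[Tuple[float, float]] = None,
    events: Optional[EventLog] = None,
) -> DffTrace:
    """%ΔF/F0 of a single (green) channel against its own baseline mean.

    Used for restrained-male recordings without a red reference.
    """
    green = np.asarray(green, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if green.size != time_s.size:
        raise ValueError("green and time_s must have equal length")
    events = events if events is not None else EventLog()
    if f0_window is None:
        f0_window = default_f0_window(time_s, events)
    mask = _window_mask(time_s, f0_window)
    f0 = float(green[mask].mean())
    if not f0 > 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    dff = 100.0 * (green - f0) / f0
    return DffTrace(time_s, dff, f0, events)


def restrained_summary(dff: DffTrace, window_s: float = 60.0) -> dict:
    """Summary for cover-slip-restrained recordings.

    Returns the largest absolute %ΔF/F0 excursion from the value at time
    point 0 within the window, and the SD of %ΔF/F0 over the window.
    """
    t0 = float(dff.time_s[0])
    if t0 + window_s > float(dff.time_s[-1]) + dff.dt_s:
        raise ValueError(
            f"window of {window_s} s exceeds the {dff.time_s[-1] - t0:.1f} s trace"
        )
    mask = (dff.time_s >= t0) & (dff.time_s < t0 + window_s)
    seg = dff.dff_percent[mask]
    return {
        "max_change_from_t0": float(np.max(np.abs(seg - seg[0]))),
        "sd": float(np.std(seg)),
    }
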