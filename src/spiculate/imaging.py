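"""Image-level fixtures: render a trace into a 2-channel frame stack and
extract ROI means back out.

``render_frames`` produces frames where the mean pixel value inside the ROI
equals the trace value at that frame and all other pixels sit at the
background level, mirroring how ROI mean gray levels are measured on real
recordings (with the ROI moved frame-by-frame to follow the animal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import DualChannelTrace

__all__ = ["RoiBox", "ImageStack", "render_frames", "extract_roi_means"]


@dataclass(frozen=True)
class RoiBox:
    """Inclusive pixel box, 0-based: columns [cx, cx+width), rows [cy, cy+height)."""

    cx: int
    cy: int
    width: int
    height: int

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must be at least 1x1 pixels")

    def slices(self) -> Tuple[slice, slice]:
        return (slice(self.cy, self.cy + self.height), slice(self.cx, self.cx + self.width))

    def inside(self, frame_shape: Tuple[int, int]) -> bool:
        h, w = frame_shape
        return (
            0 <= self.cy and self.cy + self.height <= h
            and 0 <= self.cx and self.cx + self.width <= w
        )

    def shifted(self, dx: int, dy: int) -> "RoiBox":
        return RoiBox(self.cx + dx, self.cy + dy, self.width, self.height)


@dataclass
class ImageStack:
    """Frames of shape (n_frames, 2, height, width); channel 0 green, 1 red,
    plus the per-frame ROI track used to render (or extract) the signal."""

    frames: np.ndarray
    time_s: np.ndarray
    roi_track: pd.DataFrame  # columns: frame, cx, cy, width, height

    def __post_init__(self):
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (n, 2, height, width)")
        if self.frames.shape[0] != self.time_s.size:
            raise ValueError("one frame per time sample required")


def _track_frame(track: pd.DataFrame) -> pd.DataFrame:
    required = ["frame", "cx", "cy", "width", "height"]
    missing = [c for c in required if c not in track.columns]
    if missing:
        raise ValueError(f"ROI track missing columns: {missing}")
    return track


def render_frames(
    trace: DualChannelTrace,
    roi: RoiBox,
    frame_shape: Tuple[int, int] = (48, 64),
    drift_path: Optional[Sequence[Tuple[int, int]]] = None,
    background_level: Optional[float] = None,
) -> ImageStack:
    """Render a dual-channel trace into a synthetic frame stack.

    The ROI is filled uniformly with the trace value for that frame (so its
    mean equals the trace value exactly); the rest of the frame sits at the
    background level (taken from the trace's background series when
    present).  ``drift_path`` gives per-frame (dx, dy) offsets of the ROI
    center; an empty path means a static ROI.  The drifted ROI must stay
    inside the frame.
    """
    n = len(trace)
    if drift_path is not None and len(drift_path) not in (0, n):
        raise ValueError("drift_path must be empty or provide one offset per frame")
    offsets = list(drift_path) if drift_path else [(0, 0)] * n
    frames = np.empty((n, 2, *frame_shape), dtype=float)
    rows = []
    for i in range(n):
        box = roi.shifted(*offsets[i])
        if not box.inside(frame_shape):
            raise ValueError(f"ROI exits the frame at frame {i}")
        for ch, (signal, bg) in enumerate(
            [(trace.green, trace.green_bg), (trace.red, trace.red_bg)]
        ):
            level = (
                background_level
                if background_level is not None
                else (float(bg[i]) if bg is not None else 0.0)
            )
            frames[i, ch] = level
            frames[i, ch][box.slices()] = signal[i]
        rows.append(
            {"frame": i, "cx": box.cx, "cy": box.cy, "width": box.width, "height": box.height}
        )
    return ImageStack(frames, trace.time_s.copy(), pd.DataFrame(rows))


def extract_roi_means(
    stack: ImageStack,
    roi_track: Optional[pd.DataFrame] = None,
    bg_roi: Optional[RoiBox] = None,
) -> DualChannelTrace:
    """Mean gray level inside the tracked ROI per frame and channel.

    ``roi_track`` defaults to the stack's own (ground-truth) track; passing a
    stale track emulates a mistracked ROI.  Background ROI means are taken
    from ``bg_roi`` when given, else from the top-left frame corner pixel
    (which render_frames leaves at background level).
    """
    track = _track_frame(roi_track if roi_track is not None else stack.roi_track)
    track = track.sort_values("frame").reset_index(drop=True)
    n = stack.frames.shape[0]
    if len(track) != n:
        raise ValueError("ROI track must cover every frame")
    frame_shape = stack.frames.shape[2:]
    green = np.empty(n)
    red = np.empty(n)
    green_bg = np.empty(n)
    red_bg = np.empty(n)
    for i, row in track.iterrows():
        box = RoiBox(int(row.cx), int(row.cy), int(row.width), int(row.height))
        if not box.inside(frame_shape):
            raise ValueError(f"ROI outside the frame at frame {i}")
        sl = box.slices()
        green[i] = stack.frames[i, 0][sl].mean()
        red[i] = stack.frames[i, 1][sl].mean()
        if bg_roi is not None:
            bsl = bg_roi.slices()
            green_bg[i] = stack.frames[i, 0][bsl].mean()
            red_bg[i] = stack.frames[i, 1][bsl].mean()
        else:
            green_bg[i] = stack.frames[i, 0][0, 0]
            red_bg[i] = stack.frames[i, 1][0, 0]
    return DualChannelTrace(stack.time_s, green, red, green_bg, red_bg)
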