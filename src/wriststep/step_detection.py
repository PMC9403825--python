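"""Slope-change peak detection: the step counter proper.

A step is a local maximum of the filtered magnitude: the discrete slope
changes from positive to negative and the value at the peak exceeds the
cut-off threshold.  Tie handling: a zero slope inherits the sign of the
last nonzero slope, so a flat-topped peak counts once, attributed to
the first sample of its plateau.  The first and last samples of a
window can never be peaks (slope change is undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import ActivityLevel, StepConfig, ValidationError
from .preprocess import filter_stream, segment_windows

__all__ = ["PeakEvent", "detect_peaks", "count_steps_window"]


@dataclass(frozen=True)
class PeakEvent:
    """One detected step: sample index within the window and peak height (g)."""

    sample_index: int
    height: float


def detect_peaks(filtered: np.ndarray, threshold: float) -> list[PeakEvent]:
    """Find slope-change maxima above ``threshold`` in a filtered window.

    Windows shorter than 3 samples contain no detectable peak and
    return an empty list.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    v = np.asarray(filtered, dtype=float)
    n = v.size
    if n < 3:
        return []
    d = np.diff(v)
    signs = np.sign(d)
    # zero slopes inherit the last nonzero slope's sign (plateau collapse);
    # forward-fill via running maximum of the last nonzero index
    nz = signs != 0
    idx_src = np.where(nz, np.arange(signs.size), -1)
    np.maximum.accumulate(idx_src, out=idx_src)
    signs = np.where(idx_src >= 0, signs[np.maximum(idx_src, 0)], 0.0)
    change = (signs[:-1] > 0) & (signs[1:] < 0)  # slope + -> - at k = position+1
    peaks: list[PeakEvent] = []
    for k in np.flatnonzero(change) + 1:  # k ranges over 1 .. n-2
        idx = int(k)
        while idx > 0 and d[idx - 1] == 0.0:  # attribute to first plateau sample
            idx -= 1
        if v[idx] > threshold:
            peaks.append(PeakEvent(sample_index=idx, height=float(v[idx])))
    return peaks


def count_steps_window(
    filtered_window: np.ndarray,
    activity: ActivityLevel,
    threshold: float,
) -> int:
    """Steps in one already-filtered 5-second window.

    Low-activity windows are gated to 0 regardless of signal content;
    that is what suppresses random hand motion.
    """
    if not activity.counts_steps:
        return 0
    return len(detect_peaks(filtered_window, threshold))
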