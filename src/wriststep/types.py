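"""Domain types shared across the package.

The central object is :class:`AccelSeries`, a uniformly sampled wrist
acceleration-magnitude stream (in g) for one calendar day, carrying
per-hour wear flags.  Daily totals from either device are held in
:class:`DailySummary`; per-window classification/counting results in
:class:`WindowResult`; the step-detector configuration in
:class:`StepConfig`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "ActivityLevel",
    "AccelSeries",
    "WindowResult",
    "DailySummary",
    "StepConfig",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class ActivityLevel(str, enum.Enum):
    """Physical-activity intensity of a 5-second window."""

    LOW = "low"
    MODERATE = "moderate"
    VIGOROUS = "vigorous"

    @property
    def counts_steps(self) -> bool:
        """Only moderate and vigorous windows open the step-counting gate."""
        return self is not ActivityLevel.LOW


@dataclass(frozen=True)
class AccelSeries:
    """Uniformly sampled acceleration-magnitude stream for one day.

    Parameters
    ----------
    sampling_rate:
        Samples per second; the device logs at 20 Hz.
    samples:
        Acceleration magnitude in g, one value per sample tick.
    day_id:
        ISO-8601 calendar date the stream belongs to.
    t0:
        Seconds since local midnight of the first sample.
    wear_flags:
        Mapping hour-of-day -> worn?  Must cover every hour the series
        spans; hours not spanned may be present (e.g. a full-day record).
    """

    sampling_rate: float
    samples: np.ndarray
    day_id: str = "2021-01-01"
    t0: float = 0.0
    wear_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        arr = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", arr)
        if arr.ndim != 1:
            raise ValidationError("samples must be a 1-D magnitude array")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("samples contain non-finite values")
        if self.t0 < 0 or not math.isfinite(self.t0):
            raise ValidationError(f"t0 must be finite and non-negative, got {self.t0}")
        flags = dict(self.wear_flags) if self.wear_flags else {h: True for h in self.hours_spanned()}
        missing = [h for h in self.hours_spanned() if h not in flags]
        if missing:
            raise ValidationError(f"wear_flags missing hours {missing}")
        object.__setattr__(self, "wear_flags", flags)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Length of the stream in seconds."""
        return len(self) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds since local midnight."""
        return self.t0 + np.arange(len(self)) / self.sampling_rate

    def hours_spanned(self) -> list[int]:
        if len(self) == 0:
            return []
        last_t = self.t0 + (len(self) - 1) / self.sampling_rate
        return list(range(int(self.t0 // 3600), int(last_t // 3600) + 1))

    def wear_minutes(self) -> int:
        """Minutes in hours flagged as worn (60 per worn hour)."""
        return 60 * sum(bool(v) for v in self.wear_flags.values())


@dataclass(frozen=True)
class WindowResult:
    """Classification and step count for one 5-second window."""

    window_index: int
    activity: ActivityLevel
    steps: int

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValidationError("steps must be non-negative")
        if self.activity is ActivityLevel.LOW and self.steps != 0:
            raise ValidationError("low-activity windows must report 0 steps")


@dataclass(frozen=True)
class DailySummary:
    """Per-device, per-day step total.

    ``wear_minutes`` is meaningful for the watch only (the reference
    device reports daily steps but no wear time); it defaults to None.
    """

    day_id: str
    device: str  # "watch" or "reference"
    steps: int
    wear_minutes: int | None = None

    def __post_init__(self) -> None:
        if self.device not in ("watch", "reference"):
            raise ValidationError(f"device must be 'watch' or 'reference', got {self.device!r}")
        if self.steps < 0:
            raise ValidationError(f"steps must be >= 0, got {self.steps}")
        if self.wear_minutes is not None and not 0 <= self.wear_minutes <= 1440:
            raise ValidationError(f"wear_minutes must lie in [0, 1440], got {self.wear_minutes}")


@dataclass(frozen=True)
class StepConfig:
    """Parameters of the step-detection pipeline.

    Defaults follow the on-device algorithm: 5-second windows at 20 Hz,
    zero-meaning against the preceding 20 samples, a 3-sample
    moving-average filter, and a peak cut-off threshold in g.  The
    candidate grid is what the tuning procedure searches over.
    """

    window_seconds: float = 5.0
    zero_mean_history: int = 20
    smooth_length: int = 3
    peak_threshold: float = 0.10
    candidate_thresholds: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20, 0.25)

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValidationError("window_seconds must be positive")
        if self.zero_mean_history < 1 or self.smooth_length < 1:
            raise ValidationError("filter lengths must be positive integers")
        if not math.isfinite(self.peak_threshold):
            raise ValidationError("peak_threshold must be finite")
        cand = tuple(float(c) for c in self.candidate_thresholds)
        if cand and any(b <= a for a, b in zip(cand, cand[1:])):
            raise ValidationError("candidate_thresholds must be strictly increasing")
        object.__setattr__(self, "candidate_thresholds", cand)

    def window_samples(self, sampling_rate: float) -> int:
        n = sampling_rate * self.window_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"window of {self.window_seconds}s is not an integer number of samples at {sampling_rate} Hz"
            )
        return int(round(n))


def as_magnitude(ax: float, ay: float, az: float) -> float:
    """Euclidean norm of a 3-axis acceleration sample, in g."""
    if not all(math.isfinite(v) for v in (ax, ay, az)):
        raise ValidationError("acceleration components must be finite")
    return math.sqrt(ax * ax + ay * ay + az * az)
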