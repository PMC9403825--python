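"""Signal conditioning ahead of peak detection.

The detector operates on the acceleration magnitude after two causal
stages: *zero-meaning* (subtract the mean of the preceding 20 samples,
removing the 1 g gravity baseline and slow drift) and a *moving
average* over the 3 preceding samples (suppressing sample-level
jitter).  Both are strictly causal — each output depends only on
samples before the current one — so they can run on-device as the
stream arrives.

Warm-up conventions, where fewer preceding samples exist than the
filter length asks for:

* zero-mean: subtract the mean of all available preceding samples;
  the very first sample maps to 0.
* moving average: average the available preceding samples; the very
  first sample passes through unchanged.

Filters run over the whole day's stream *before* it is cut into
5-second windows, so window boundaries introduce no edge artifacts.
"""

from __future__ import annotations

import numpy as np

from .types import AccelSeries, StepConfig, ValidationError

__all__ = ["magnitude", "zero_mean", "moving_average", "filter_stream", "segment_windows"]


def magnitude(ax: float, ay: float, az: float) -> float:
    """Euclidean norm of a 3-axis sample, in g (orientation-invariant)."""
    from .types import as_magnitude

    return as_magnitude(ax, ay, az)


def _preceding_mean(values: np.ndarray, length: int) -> np.ndarray:
    """mean(values[max(0, i-length) .. i-1]) for every i; 0/0 treated later."""
    n = values.size
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - length, 0)
    counts = idx - lo
    sums = csum[idx] - csum[lo]
    out = np.zeros(n)
    np.divide(sums, counts, out=out, where=counts > 0)
    return out


def zero_mean(values: np.ndarray | AccelSeries, history: int = 20) -> np.ndarray:
    """Subtract the rolling mean of the preceding ``history`` samples.

    out[i] = x[i] - mean(x[max(0, i-history) .. i-1]); out[0] = 0.
    """
    if isinstance(values, AccelSeries):
        values = values.samples
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot zero-mean an empty series")
    if history < 1:
        raise ValidationError("history must be >= 1")
    out = x - _preceding_mean(x, history)
    out[0] = 0.0
    return out


def moving_average(values: np.ndarray, length: int = 3) -> np.ndarray:
    """Replace each sample with the mean of its ``length`` preceding samples.

    out[i] = mean(x[max(0, i-length) .. i-1]); out[0] = x[0].
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot smooth an empty series")
    if length < 1:
        raise ValidationError("length must be >= 1")
    out = _preceding_mean(x, length)
    out[0] = x[0]
    return out


def filter_stream(series: AccelSeries, config: StepConfig | None = None) -> np.ndarray:
    """Full conditioning chain: zero-mean then moving average.

    Returns an array aligned 1:1 with ``series.samples``.
    """
    config = config or StepConfig()
    return moving_average(zero_mean(series.samples, config.zero_mean_history), config.smooth_length)


def segment_windows(values: np.ndarray, sampling_rate: float, window_seconds: float = 5.0) -> list[np.ndarray]:
    """Cut a stream into consecutive non-overlapping fixed-length windows.

    A trailing partial window is dropped; a stream shorter than one
    window yields an empty list.
    """
    n_win = sampling_rate * window_seconds
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValidationError(
            f"{window_seconds}s windows are not an integer number of samples at {sampling_rate} Hz"
        )
    n_win = int(round(n_win))
    x = np.asarray(values, dtype=float)
    n_full = x.size // n_win
    return [x[i * n_win : (i + 1) * n_win] for i in range(n_full)]
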