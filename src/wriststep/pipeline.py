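"""End-to-end daily step counting and the cut-off tuning procedure.

A day is processed as: condition the whole magnitude stream (zero-mean
then moving average), cut both the raw and the filtered stream into
5-second windows, classify each raw window's activity level, and count
slope-change peaks in the corresponding filtered window only when the
level is moderate or vigorous.  Daily steps are the sum over windows.

Tuning replays the field-study procedure: count every day under each
candidate cut-off, compare against the reference device's daily totals
by percentage difference, and keep the candidate whose mean percentage
difference is smallest in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .activity_gate import ActivityModel, classify_activity, extract_features
from .preprocess import filter_stream, segment_windows
from .step_detection import count_steps_window, detect_peaks
from .types import AccelSeries, DailySummary, StepConfig, ValidationError, WindowResult

__all__ = ["count_steps_day", "TuningResult", "tune_threshold"]


def count_steps_day(
    series: AccelSeries,
    config: StepConfig | None = None,
    model: ActivityModel | None = None,
) -> tuple[DailySummary, list[WindowResult]]:
    """Count a full day of steps; returns the daily total and per-window detail.

    ``model=None`` disables the activity gate (every window is treated
    as moderate) — useful for inspecting the raw detector.

    Peak detection runs over the whole day's filtered stream (the
    device processes a continuous stream; windows exist only for
    classification), and each peak is attributed to the 5-second window
    containing it, so window boundaries cost no steps.  Peaks falling
    in a trailing partial window are dropped with it.
    """
    config = config or StepConfig()
    filtered = filter_stream(series, config)
    raw_windows = segment_windows(series.samples, series.sampling_rate, config.window_seconds)
    n_win_samples = config.window_samples(series.sampling_rate)

    peaks = detect_peaks(filtered, config.peak_threshold)
    per_window = [0] * len(raw_windows)
    for p in peaks:
        w = p.sample_index // n_win_samples
        if w < len(per_window):
            per_window[w] += 1

    results: list[WindowResult] = []
    from .types import ActivityLevel

    for i, raw_w in enumerate(raw_windows):
        if model is None:
            level = ActivityLevel.MODERATE
        else:
            level = classify_activity(extract_features(raw_w), model)
        steps = per_window[i] if level.counts_steps else 0
        results.append(WindowResult(window_index=i, activity=level, steps=steps))

    summary = DailySummary(
        day_id=series.day_id,
        device="watch",
        steps=sum(r.steps for r in results),
        wear_minutes=min(series.wear_minutes(), 1440),
    )
    return summary, results


@dataclass(frozen=True)
class TuningResult:
    """Per-candidate agreement statistics and the selected cut-off.

    ``rows`` maps candidate threshold (g) -> dict with keys
    ``mean_pct_diff``, ``sd_pct_diff``, ``r2`` (NaN when undefined) and
    ``n_days``.  Selection minimizes |mean_pct_diff|; ties go to the
    smaller threshold.
    """

    rows: dict[float, dict[str, float]]
    selected_threshold: float
    selection_rule: str = "min_abs_mean_pct_diff"

    def __post_init__(self) -> None:
        if self.selected_threshold not in self.rows:
            raise ValidationError("selected threshold must be one of the candidates")


def tune_threshold(
    watch_series: list[AccelSeries],
    reference: list[DailySummary],
    candidates: list[float] | None = None,
    config: StepConfig | None = None,
    model: ActivityModel | None = None,
) -> TuningResult:
    """Evaluate every candidate peak cut-off against the reference device.

    For each candidate, all days are re-counted and paired with the
    reference summaries by date; the per-day percentage difference
    ``100 (watch - ref)/ref`` is summarized (mean, sample SD) together
    with the R² of watch-on-reference regression when computable.
    """
    from scipy import stats

    from .evaluation import pct_diff

    config = config or StepConfig()
    cands = [float(c) for c in (candidates if candidates is not None else config.candidate_thresholds)]
    if not cands:
        raise ValidationError("candidate list must be non-empty")
    ref_by_day = {s.day_id: s for s in reference if s.device == "reference"}
    paired_days = [s for s in watch_series if s.day_id in ref_by_day]
    if not paired_days:
        raise ValidationError("no watch days pair with the reference summaries")

    rows: dict[float, dict[str, float]] = {}
    for cand in cands:
        cfg = replace(config, peak_threshold=cand)
        diffs, xs, ys = [], [], []
        for series in paired_days:
            summary, _ = count_steps_day(series, cfg, model)
            ref = ref_by_day[series.day_id]
            if ref.steps == 0:
                continue
            diffs.append(pct_diff(summary.steps, ref.steps))
            xs.append(ref.steps)
            ys.append(summary.steps)
        if not diffs:
            raise ValidationError("no paired days with nonzero reference steps")
        d = np.asarray(diffs)
        r2 = float("nan")
        if len(xs) >= 3 and len(set(xs)) > 1:
            r2 = float(stats.linregress(xs, ys).rvalue ** 2)
        rows[cand] = {
            "mean_pct_diff": float(np.mean(d)),
            "sd_pct_diff": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            "r2": r2,
            "n_days": len(diffs),
        }

    selected = min(cands, key=lambda c: (abs(rows[c]["mean_pct_diff"]), c))
    return TuningResult(rows=rows, selected_threshold=selected)
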