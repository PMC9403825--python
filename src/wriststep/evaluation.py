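"""Device-agreement statistics for paired watch/reference days.

Implements the field-study analysis protocol: wear-time day filtering
(watch worn ≥ 75% of a 15-hour day, i.e. ≥ 675 minutes; reference
counted as worn when its daily steps exceed 100), percentage
difference, ordinary-least-squares regression of watch on reference,
and Bland-Altman agreement with limits at mean ± 2 SD of the per-day
differences (sample SD, n−1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .types import DailySummary, ValidationError

__all__ = [
    "WearCriteria",
    "AgreementReport",
    "filter_worn_days",
    "pct_diff",
    "error_rate_vs_truth",
    "fit_regression",
    "bland_altman",
    "evaluate_agreement",
]


@dataclass(frozen=True)
class WearCriteria:
    """Day-inclusion rules for device comparison.

    The watch detects wear hourly: a day counts when it was worn for at
    least ``min_wear_fraction`` of a ``day_hours``-hour waking day
    (0.75 × 15 h = 675 minutes, inclusive).  The reference device only
    reports daily steps, so it counts as worn when its step count is
    strictly greater than ``reference_min_steps``.
    """

    day_hours: float = 15.0
    min_wear_fraction: float = 0.75
    reference_min_steps: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.min_wear_fraction <= 1:
            raise ValidationError("min_wear_fraction must lie in (0, 1]")
        if self.day_hours <= 0 or self.reference_min_steps <= 0:
            raise ValidationError("thresholds must be positive")

    @property
    def wear_minutes_threshold(self) -> float:
        """Minimum watch wear minutes for a day to count (675 by default)."""
        return self.min_wear_fraction * self.day_hours * 60.0


def filter_worn_days(
    watch: Sequence[DailySummary],
    reference: Sequence[DailySummary],
    criteria: WearCriteria | None = None,
) -> list[tuple[DailySummary, DailySummary]]:
    """Date-aligned (watch, reference) pairs for days both devices were worn.

    Keeps a date iff the watch was worn at least the wear-minute
    threshold (inclusive) AND the reference's steps strictly exceed its
    minimum.  Order of the inputs does not matter; output is sorted by
    date.  An empty result is not an error.
    """
    criteria = criteria or WearCriteria()
    watch_by_day = {s.day_id: s for s in watch}
    ref_by_day = {s.day_id: s for s in reference}
    pairs = []
    for day in sorted(set(watch_by_day) & set(ref_by_day)):
        w, r = watch_by_day[day], ref_by_day[day]
        wear = w.wear_minutes if w.wear_minutes is not None else 0
        if wear >= criteria.wear_minutes_threshold and r.steps > criteria.reference_min_steps:
            pairs.append((w, r))
    return pairs


def pct_diff(watch_steps: float, reference_steps: float) -> float:
    """Percentage difference, 100 × (watch − reference) / reference."""
    if reference_steps <= 0:
        raise ValidationError("reference steps must be positive for a percentage difference")
    return 100.0 * (watch_steps - reference_steps) / reference_steps


def error_rate_vs_truth(estimated: float, truth: float) -> float:
    """Lab-study error rate against video-validated counts.

    Identical in form to :func:`pct_diff` with the ground truth as the
    denominator.
    """
    return pct_diff(estimated, truth)


def fit_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS of watch steps (y) on reference steps (x): slope, intercept, r².

    r² equals the squared Pearson correlation.  Needs ≥ 3 pairs and
    non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("regression needs at least 3 (x, y) pairs")
    if np.all(x == x[0]):
        raise ValidationError("regression is degenerate: x is constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, float, list[int]]:
    """Bland-Altman limits for per-day (watch, reference) step pairs.

    Differences d = watch − reference; limits = mean(d) ± 2·SD(d) with
    sample (n−1) SD.  Returns (mean_diff, upper, lower, outlier
    indices), where outliers are days with |d − mean| > 2 SD (both
    tails).
    """
    if len(pairs) < 2:
        raise ValidationError("Bland-Altman needs at least 2 pairs")
    d = np.asarray([w - r for w, r in pairs], dtype=float)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    upper, lower = mean + 2 * sd, mean - 2 * sd
    outliers = [i for i, v in enumerate(d) if abs(v - mean) > 2 * sd]
    return mean, upper, lower, outliers


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one set of paired device-days."""

    n_days: int
    slope: float
    intercept: float
    r2: float
    mean_pct_diff: float
    sd_pct_diff: float
    ba_mean_diff: float
    ba_upper: float
    ba_lower: float
    outlier_days: tuple[str, ...] = ()

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["outlier_days"] = list(self.outlier_days)
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def evaluate_agreement(
    watch: Sequence[DailySummary],
    reference: Sequence[DailySummary],
    criteria: WearCriteria | None = None,
) -> AgreementReport:
    """Run the whole protocol: wear filter, % difference, OLS, Bland-Altman."""
    pairs = filter_worn_days(watch, reference, criteria)
    if len(pairs) < 3:
        raise ValidationError(f"only {len(pairs)} worn day-pairs; need >= 3 for the agreement analysis")
    days = [w.day_id for w, _ in pairs]
    x = [r.steps for _, r in pairs]
    y = [w.steps for w, _ in pairs]
    slope, intercept, r2 = fit_regression(x, y)
    diffs = np.array([pct_diff(yy, xx) for xx, yy in zip(x, y)])
    ba_mean, ba_up, ba_lo, out_idx = bland_altman(list(zip(y, x)))
    return AgreementReport(
        n_days=len(pairs),
        slope=slope,
        intercept=intercept,
        r2=r2,
        mean_pct_diff=float(np.mean(diffs)),
        sd_pct_diff=float(np.std(diffs, ddof=1)),
        ba_mean_diff=ba_mean,
        ba_upper=ba_up,
        ba_lower=ba_lo,
        outlier_days=tuple(days[i] for i in out_idx),
    )


def plot_agreement(
    watch: Sequence[DailySummary],
    reference: Sequence[DailySummary],
    path: str | Path,
    criteria: WearCriteria | None = None,
) -> None:
    """Scatter + Bland-Altman panel for paired worn days (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = filter_worn_days(watch, reference, criteria)
    x = np.array([r.steps for _, r in pairs], dtype=float)
    y = np.array([w.steps for w, _ in pairs], dtype=float)
    mean_d, up, lo, _ = bland_altman(list(zip(y, x)))
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(x, y, s=12)
    slope, intercept, r2 = fit_regression(x, y)
    xs = np.linspace(x.min(), x.max(), 2)
    ax1.plot(xs, slope * xs + intercept, "k-", lw=1)
    ax1.set_xlabel("reference daily steps")
    ax1.set_ylabel("watch daily steps")
    ax1.set_title(f"$R^2$ = {r2:.3f}")
    ax2.scatter((x + y) / 2, y - x, s=12)
    ax2.axhline(mean_d, color="tab:blue")
    for lim in (up, lo):
        ax2.axhline(lim, color="tab:red", ls="--")
    ax2.set_xlabel("mean of devices (steps)")
    ax2.set_ylabel("watch − reference (steps)")
    ax2.set_title("Bland-Altman (mean ± 2 SD)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
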