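"""Synthetic 20 Hz wrist acceleration-magnitude streams with known steps.

No raw accelerometer data are deposited with the study this tool
re-implements, so every stage is exercised against simulated signals
with exact ground truth.  The signal model is deliberately minimal: a
1 g gravity baseline, one raised-cosine pulse per step (amplitude drawn
per step), and additive Gaussian sensor noise.  That is precisely the
structure the detector consumes — magnitude peaks at step cadence — and
anything biomechanically richer would be unverifiable.

Patterns mirror the four laboratory walking conditions plus the
confounders the activity gate exists to reject:

========== ======================= ==========================================
pattern     intensity (truth)       signal
========== ======================= ==========================================
normal      moderate                cadence 100 steps/min, pulse amp 0.30 g
fast        vigorous                cadence 130, amp 0.45 g (over-counts)
stairs      moderate                cadence 80, amp 0.18 g (under-counts)
intermittent moderate (walk parts)  alternating 20 s walk / 10 s rest
rest        low                     baseline + small noise, no steps
hand_motion low                     slow smooth drift, no steps
nonwear     low                     baseline + tiny noise, wear flag off
========== ======================= ==========================================

All randomness flows from one explicit seed per scenario through a
named numpy generator; identical scenarios are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import AccelSeries, ActivityLevel, DailySummary, StepConfig, ValidationError

__all__ = [
    "GaitScenario",
    "GroundTruth",
    "PATTERNS",
    "simulate_bout",
    "simulate_day",
    "simulate_reference_device",
    "calibrate_defaults",
]

#: per-pattern defaults: cadence (steps/min), pulse amplitude mean/SD (g),
#: noise SD (g), ground-truth intensity while stepping
PATTERNS: dict[str, dict] = {
    "normal": dict(cadence=100.0, amp=0.30, amp_sd=0.05, noise_sd=0.02, level=ActivityLevel.MODERATE),
    "fast": dict(cadence=130.0, amp=0.45, amp_sd=0.07, noise_sd=0.02, level=ActivityLevel.VIGOROUS),
    "stairs": dict(cadence=80.0, amp=0.18, amp_sd=0.03, noise_sd=0.02, level=ActivityLevel.MODERATE),
    "intermittent": dict(cadence=100.0, amp=0.30, amp_sd=0.05, noise_sd=0.02, level=ActivityLevel.MODERATE),
    "rest": dict(cadence=0.0, amp=0.0, amp_sd=0.0, noise_sd=0.01, level=ActivityLevel.LOW),
    "hand_motion": dict(cadence=0.0, amp=0.05, amp_sd=0.0, noise_sd=0.01, level=ActivityLevel.LOW),
    "nonwear": dict(cadence=0.0, amp=0.0, amp_sd=0.0, noise_sd=0.002, level=ActivityLevel.LOW),
}

PULSE_SECONDS = 0.3  # raised-cosine step pulse width
BASELINE_G = 1.0  # gravity


@dataclass(frozen=True)
class GaitScenario:
    """Specification of one simulated bout (or, via ``schedule``, a day).

    ``cadence`` in steps/min; ``step_amplitude``/``amplitude_sd`` are the
    mean and SD of per-step pulse peak heights in g; ``noise_sd`` the
    additive Gaussian sensor noise in g.  ``None`` fields fall back to
    the pattern's defaults.  ``schedule`` is an ordered list of
    ``(pattern, duration_seconds)`` bouts for full-day synthesis.
    """

    pattern: str = "normal"
    duration: float = 60.0
    seed: int = 0
    cadence: float | None = None
    step_amplitude: float | None = None
    amplitude_sd: float | None = None
    noise_sd: float | None = None
    sampling_rate: float = 20.0
    day_id: str = "2021-01-01"
    schedule: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}; choose from {sorted(PATTERNS)}")
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.schedule is not None:
            object.__setattr__(self, "schedule", tuple((str(p), float(d)) for p, d in self.schedule))

    def resolved(self) -> dict:
        """Pattern defaults overlaid with any explicit overrides."""
        d = PATTERNS[self.pattern]
        return dict(
            cadence=self.cadence if self.cadence is not None else d["cadence"],
            amp=self.step_amplitude if self.step_amplitude is not None else d["amp"],
            amp_sd=self.amplitude_sd if self.amplitude_sd is not None else d["amp_sd"],
            noise_sd=self.noise_sd if self.noise_sd is not None else d["noise_sd"],
            level=d["level"],
        )


@dataclass(frozen=True)
class GroundTruth:
    """Exact step events and per-window intensity labels of a simulation."""

    step_times: np.ndarray  # seconds, strictly increasing
    window_labels: tuple[ActivityLevel, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.step_times, dtype=float)
        object.__setattr__(self, "step_times", t)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("step_times must be strictly increasing")

    @property
    def total_steps(self) -> int:
        return int(self.step_times.size)


def _step_times(rng: np.random.Generator, cadence: float, duration: float) -> np.ndarray:
    """Step event times at the given cadence with ±10% interval jitter."""
    if cadence <= 0:
        return np.empty(0)
    base = 60.0 / cadence
    times = []
    t = base / 2  # first step mid-way through the first interval
    while t < duration - PULSE_SECONDS / 2:
        times.append(t)
        t += base * (1.0 + rng.uniform(-0.1, 0.1))
    return np.asarray(times)


def _render(
    rng: np.random.Generator,
    scenario: GaitScenario,
    t_offset: float,
) -> tuple[np.ndarray, np.ndarray, ActivityLevel]:
    """Magnitude samples, step times (absolute) and intensity for one bout."""
    p = scenario.resolved()
    fs = scenario.sampling_rate
    n = int(round(scenario.duration * fs))
    t = np.arange(n) / fs
    m = np.full(n, BASELINE_G)

    if scenario.pattern == "intermittent":
        # alternating 20 s walk / 10 s rest sub-bouts
        steps_local: list[float] = []
        pos = 0.0
        walking = True
        while pos < scenario.duration:
            seg = min(20.0 if walking else 10.0, scenario.duration - pos)
            if walking:
                sub = _step_times(rng, p["cadence"], seg) + pos
                steps_local.extend(sub)
            pos += seg
            walking = not walking
        step_t = np.asarray(steps_local)
    else:
        step_t = _step_times(rng, p["cadence"], scenario.duration)

    for st in step_t:
        amp = max(rng.normal(p["amp"], p["amp_sd"]), 0.05) if p["amp_sd"] > 0 else p["amp"]
        half = PULSE_SECONDS / 2
        i0 = max(int(np.ceil((st - half) * fs)), 0)
        i1 = min(int(np.floor((st + half) * fs)), n - 1)
        tt = t[i0 : i1 + 1] - st
        m[i0 : i1 + 1] += amp * 0.5 * (1.0 + np.cos(np.pi * tt / half))

    if scenario.pattern == "hand_motion":
        # slow, smooth wrist drift: two incommensurate low-frequency tones
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        m = m + p["amp"] * (np.sin(2 * np.pi * 0.4 * t + ph1) + 0.5 * np.sin(2 * np.pi * 0.23 * t + ph2))

    if p["noise_sd"] > 0:
        m = m + rng.normal(0.0, p["noise_sd"], n)
    m = np.maximum(m, 0.0)
    return m, step_t + t_offset, p["level"]


def _window_labels(
    step_times: np.ndarray,
    levels: list[tuple[float, float, ActivityLevel]],
    n_samples: int,
    fs: float,
    t0: float,
    window_seconds: float = 5.0,
) -> tuple[ActivityLevel, ...]:
    """A window is labeled at its bout's intensity iff it contains a step."""
    n_win = int(n_samples // (fs * window_seconds))
    labels = []
    for w in range(n_win):
        lo = t0 + w * window_seconds
        hi = lo + window_seconds
        in_win = step_times[(step_times >= lo) & (step_times < hi)]
        if in_win.size == 0:
            labels.append(ActivityLevel.LOW)
            continue
        lvl = ActivityLevel.MODERATE
        for b_lo, b_hi, b_lvl in levels:
            if b_lo <= in_win[0] < b_hi:
                lvl = b_lvl
                break
        labels.append(lvl)
    return tuple(labels)


def simulate_bout(scenario: GaitScenario) -> tuple[AccelSeries, GroundTruth]:
    """Simulate a single-pattern bout; returns the stream and exact truth."""
    rng = np.random.default_rng(scenario.seed)
    m, step_t, level = _render(rng, scenario, t_offset=0.0)
    worn = scenario.pattern != "nonwear"
    series = AccelSeries(
        sampling_rate=scenario.sampling_rate,
        samples=m,
        day_id=scenario.day_id,
        t0=0.0,
        wear_flags={h: worn for h in range(int((len(m) - 1) / scenario.sampling_rate // 3600) + 1)},
    )
    labels = _window_labels(step_t, [(0.0, scenario.duration, level)], len(m), scenario.sampling_rate, 0.0)
    return series, GroundTruth(step_times=step_t, window_labels=labels)


def simulate_day(
    schedule: Sequence[tuple[str, float]],
    seed: int = 0,
    day_id: str = "2021-01-01",
    sampling_rate: float = 20.0,
    noise_sd: float | None = None,
) -> tuple[AccelSeries, GroundTruth, DailySummary]:
    """Concatenate scheduled bouts into one day with continuous timestamps.

    ``schedule`` is an ordered list of ``(pattern, duration_seconds)``;
    total duration must not exceed 24 h.  An hour is flagged not-worn
    iff every sample it contains comes from a ``nonwear`` bout.  The
    returned :class:`DailySummary` is the ground-truth watch-day total.
    """
    if not schedule:
        raise ValidationError("schedule must contain at least one bout")
    total = sum(d for _, d in schedule)
    if total > 86400 + 1e-9:
        raise ValidationError(f"schedule spans {total} s, more than 24 h")
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    all_steps: list[np.ndarray] = []
    levels: list[tuple[float, float, ActivityLevel]] = []
    nonwear_spans: list[tuple[float, float]] = []
    t_cursor = 0.0
    for pattern, dur in schedule:
        scen = GaitScenario(pattern=pattern, duration=dur, seed=0, sampling_rate=sampling_rate, noise_sd=noise_sd)
        m, step_t, level = _render(rng, scen, t_offset=t_cursor)
        parts.append(m)
        all_steps.append(step_t)
        levels.append((t_cursor, t_cursor + dur, level))
        if pattern == "nonwear":
            nonwear_spans.append((t_cursor, t_cursor + dur))
        t_cursor += dur
    samples = np.concatenate(parts)
    step_times = np.concatenate(all_steps) if all_steps else np.empty(0)

    n_hours = int((len(samples) - 1) / sampling_rate // 3600) + 1
    wear: dict[int, bool] = {}
    for h in range(n_hours):
        h_lo, h_hi = h * 3600.0, min((h + 1) * 3600.0, len(samples) / sampling_rate)
        covered = sum(max(0.0, min(b, h_hi) - max(a, h_lo)) for a, b in nonwear_spans)
        wear[h] = covered < (h_hi - h_lo) - 1e-9

    series = AccelSeries(sampling_rate=sampling_rate, samples=samples, day_id=day_id, t0=0.0, wear_flags=wear)
    truth = GroundTruth(
        step_times=step_times,
        window_labels=_window_labels(step_times, levels, len(samples), sampling_rate, 0.0),
    )
    summary = DailySummary(day_id=day_id, device="watch", steps=truth.total_steps, wear_minutes=series.wear_minutes())
    return series, truth, summary


def simulate_reference_device(
    truth_steps: int,
    bias_pct: float = 0.0,
    noise_pct: float = 0.0,
    seed: int = 0,
    day_id: str = "2021-01-01",
) -> DailySummary:
    """Synthetic stand-in for the commercial reference tracker.

    reference = round(truth × (1 + bias/100) × (1 + ε)), ε ~ N(0, noise/100),
    floored at 0.  Bias models the reference's systematic under/over-count;
    noise its day-to-day disagreement.
    """
    if truth_steps < 0:
        raise ValidationError("truth steps must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_pct / 100.0) if noise_pct > 0 else 0.0
    steps = int(round(truth_steps * (1.0 + bias_pct / 100.0) * (1.0 + eps)))
    return DailySummary(day_id=day_id, device="reference", steps=max(steps, 0))


def calibrate_defaults(seed: int = 0) -> tuple[StepConfig, "ActivityModel", dict]:
    """Re-enact the empirical determination of the default parameters.

    Runs a fixed battery of simulated bouts and sets (a) the
    ``sd_threshold`` gate cut-offs so walking windows pass and
    rest/hand-motion/nonwear windows are suppressed, and (b) the peak
    cut-off: the smallest candidate in the default grid for which the
    zero-noise normal-walking bout is recovered exactly *and* the
    confounder bouts produce 0 steps end-to-end.  Returns the config,
    the gate model, and a calibration report (per-candidate errors).
    """
    from .activity_gate import ActivityModel, extract_features
    from .pipeline import count_steps_day
    from .preprocess import segment_windows

    base = StepConfig()
    fs = 20.0
    # walking bouts are noise-free with nominal amplitudes (a controlled,
    # lab-style bout); confounders keep their default noise
    bouts = {}
    for name in ("normal", "fast", "stairs", "rest", "hand_motion", "nonwear"):
        if name in ("normal", "fast", "stairs"):
            scen = GaitScenario(pattern=name, duration=120.0, seed=seed, noise_sd=0.0, amplitude_sd=0.0)
        else:
            scen = GaitScenario(pattern=name, duration=120.0, seed=seed)
        bouts[name] = simulate_bout(scen)

    # gate cut-offs from per-window magnitude SDs
    def window_sds(series):
        return [extract_features(w)[1] for w in segment_windows(series.samples, fs, base.window_seconds)]

    low_sds = [sd for name in ("rest", "hand_motion", "nonwear") for sd in window_sds(bouts[name][0])]
    walk_sds = {name: window_sds(bouts[name][0]) for name in ("normal", "fast", "stairs")}
    lo_edge = max(low_sds)
    hi_edge = min(min(walk_sds["normal"]), min(walk_sds["stairs"]))
    moderate_cut = (lo_edge + hi_edge) / 2
    vigorous_cut = (float(np.mean(walk_sds["normal"])) + float(np.mean(walk_sds["fast"]))) / 2
    gate = ActivityModel(kind="sd_threshold", cutoffs=(moderate_cut, vigorous_cut))

    report: dict = {
        "gate": {"moderate_cutoff": moderate_cut, "vigorous_cutoff": vigorous_cut,
                 "max_low_sd": lo_edge, "min_walk_sd": hi_edge},
        "candidates": {},
    }
    valid: list[float] = []
    for cand in base.candidate_thresholds:
        cfg = StepConfig(
            window_seconds=base.window_seconds,
            zero_mean_history=base.zero_mean_history,
            smooth_length=base.smooth_length,
            peak_threshold=cand,
            candidate_thresholds=base.candidate_thresholds,
        )
        row = {}
        for name, (series, truth) in bouts.items():
            summary, _ = count_steps_day(series, cfg, gate)
            row[name] = {"counted": summary.steps, "truth": truth.total_steps}
        report["candidates"][cand] = row
        exact_normal = row["normal"]["counted"] == row["normal"]["truth"]
        clean = all(row[n]["counted"] == 0 for n in ("rest", "hand_motion", "nonwear"))
        if exact_normal and clean:
            valid.append(cand)
    if not valid:
        raise ValidationError("calibration failed: no candidate recovers zero-noise walking cleanly")
    # smallest valid candidate: maximal sensitivity to weak steps (older
    # adults step more softly than the nominal bout); false positives are
    # already held at zero by the gate and the confounder requirement
    chosen = min(valid)
    report["selected_threshold"] = chosen
    config = StepConfig(peak_threshold=chosen)
    return config, gate, report
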