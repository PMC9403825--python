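"""CSV readers/writers for the formats the tool consumes and emits.

Formats (UTF-8, comma-separated, header required):

* accel CSV — ``t,ax,ay,az`` (raw axes, g) or ``t,m`` (magnitude, g);
  ``t`` in seconds since local midnight, strictly increasing, uniform.
* daily CSV — ``date,steps[,wear_minutes]``; one row per day.
* wear CSV  — ``date,hour,worn`` with ``worn`` in {0,1}.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import AccelSeries, DailySummary, ValidationError, as_magnitude

__all__ = [
    "read_accel_csv",
    "write_accel_csv",
    "read_daily_csv",
    "write_daily_csv",
    "read_wear_csv",
]

ACCEL_HEADERS = (["t", "ax", "ay", "az"], ["t", "m"])


class ParseError(ValueError):
    """Malformed CSV content; message names the offending line."""


def read_accel_csv(
    path: str | Path,
    sampling_rate: float = 20.0,
    day_id: str | None = None,
    wear_flags: dict[int, bool] | None = None,
) -> AccelSeries:
    """Read an acceleration CSV into an :class:`AccelSeries`.

    Accepts either raw 3-axis rows (magnitude is computed) or a
    precomputed-magnitude column.  Timestamps must be monotone and
    uniformly spaced at ``1/sampling_rate``; gaps longer than two sample
    intervals are rejected rather than resampled, because the
    algorithm's sample-count parameters assume a fixed rate.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    cols = list(df.columns)
    if cols not in ACCEL_HEADERS:
        raise ParseError(f"{path}: header must be t,ax,ay,az or t,m; got {','.join(cols)}")
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            line = int((df[col].isna() | bad).idxmax()) + 2  # +1 header, +1 one-based
        else:
            continue
        raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")

    t = df["t"].to_numpy(dtype=float)
    dt_nominal = 1.0 / sampling_rate
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        line = int(np.argmax(diffs <= 0)) + 3
        raise ParseError(f"{path}: non-monotone timestamps at line {line}")
    if np.any(diffs > 2 * dt_nominal + 1e-9):
        line = int(np.argmax(diffs > 2 * dt_nominal + 1e-9)) + 3
        raise ParseError(f"{path}: gap exceeding 2 sample intervals at line {line}")

    if "m" in df.columns:
        m = df["m"].to_numpy(dtype=float)
        if np.any(m < 0):
            raise ParseError(f"{path}: negative magnitude")
    else:
        axes = df[["ax", "ay", "az"]].to_numpy(dtype=float)
        m = np.linalg.norm(axes, axis=1)

    return AccelSeries(
        sampling_rate=sampling_rate,
        samples=m,
        day_id=day_id or "2021-01-01",
        t0=float(t[0]),
        wear_flags=wear_flags or {},
    )


def write_accel_csv(series: AccelSeries, path: str | Path) -> None:
    """Write a magnitude series as ``t,m`` CSV."""
    df = pd.DataFrame({"t": series.times(), "m": series.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_daily_csv(path: str | Path, device: str) -> list[DailySummary]:
    """Read a ``date,steps[,wear_minutes]`` CSV into daily summaries.

    Duplicate dates and negative step counts are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    cols = list(df.columns)
    if cols[:2] != ["date", "steps"] or cols not in (
        ["date", "steps"],
        ["date", "steps", "wear_minutes"],
    ):
        raise ParseError(f"{path}: header must be date,steps[,wear_minutes]; got {','.join(cols)}")
    dates = df["date"].astype(str)
    dup = dates.duplicated()
    if dup.any():
        raise ValidationError(f"{path}: duplicate date {dates[dup.idxmax()]!r}")
    out: list[DailySummary] = []
    for _, row in df.iterrows():
        wear = None
        if "wear_minutes" in df.columns and not pd.isna(row["wear_minutes"]):
            wear = int(row["wear_minutes"])
        out.append(
            DailySummary(day_id=str(row["date"]), device=device, steps=int(row["steps"]), wear_minutes=wear)
        )
    return out


def write_daily_csv(summaries: Sequence[DailySummary], path: str | Path) -> None:
    """Write daily summaries as ``date,steps,wear_minutes`` CSV.

    Round-trips with :func:`read_daily_csv`; the ``wear_minutes`` column
    is emitted only if any summary carries it.
    """
    if not summaries:
        raise ValidationError("cannot write an empty daily CSV")
    has_wear = any(s.wear_minutes is not None for s in summaries)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "steps", "wear_minutes"] if has_wear else ["date", "steps"])
        for s in summaries:
            row = [s.day_id, s.steps]
            if has_wear:
                row.append("" if s.wear_minutes is None else s.wear_minutes)
            writer.writerow(row)


def read_wear_csv(path: str | Path) -> dict[str, dict[int, bool]]:
    """Read per-hour wear flags: mapping date -> {hour: worn}."""
    df = pd.read_csv(path)
    if list(df.columns) != ["date", "hour", "worn"]:
        raise ParseError(f"{path}: header must be date,hour,worn")
    out: dict[str, dict[int, bool]] = {}
    for _, row in df.iterrows():
        worn = int(row["worn"])
        if worn not in (0, 1):
            raise ValidationError(f"{path}: worn must be 0 or 1, got {worn}")
        out.setdefault(str(row["date"]), {})[int(row["hour"])] = bool(worn)
    return out
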