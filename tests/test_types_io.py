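"""Domain-type invariants and CSV round-trips."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wriststep import AccelSeries, DailySummary, StepConfig, ValidationError, magnitude
from wriststep.io import ParseError, read_accel_csv, read_daily_csv, read_wear_csv, write_accel_csv, write_daily_csv


@pytest.mark.parametrize(
    "axes, expected",
    [((3, 4, 0), 5.0), ((0, 0, 1), 1.0), ((1, 1, 1), math.sqrt(3))],
)
def test_magnitude_euclidean_norm(axes, expected):
    assert magnitude(*axes) == pytest.approx(expected, rel=1e-12)


def test_magnitude_rejects_non_finite():
    with pytest.raises(ValidationError):
        magnitude(float("nan"), 0, 0)


@given(st.lists(st.tuples(*[st.floats(-8, 8) for _ in range(3)]), min_size=1, max_size=50))
def test_magnitude_squared_identity(axes):
    for ax, ay, az in axes:
        m = magnitude(ax, ay, az)
        assert m >= 0
        assert m * m == pytest.approx(ax * ax + ay * ay + az * az, rel=1e-9, abs=1e-12)


def test_accel_csv_axes_to_magnitude(tmp_path):
    p = tmp_path / "a.csv"
    p.write_text("t,ax,ay,az\n0.00,3,4,0\n0.05,3,4,0\n0.10,3,4,0\n")
    series = read_accel_csv(p, sampling_rate=20)
    assert np.allclose(series.samples, [5, 5, 5])


def test_accel_csv_empty_file_is_parse_error(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("")
    with pytest.raises(ParseError):
        read_accel_csv(p)


def test_accel_csv_shuffled_timestamps_rejected(tmp_path):
    p = tmp_path / "a.csv"
    p.write_text("t,m\n0.05,1\n0.00,1\n0.10,1\n")
    with pytest.raises(ParseError, match="monotone"):
        read_accel_csv(p)


def test_accel_csv_gap_rejected(tmp_path):
    p = tmp_path / "a.csv"
    p.write_text("t,m\n0.00,1\n0.05,1\n0.50,1\n")
    with pytest.raises(ParseError, match="gap"):
        read_accel_csv(p)


def test_accel_csv_malformed_row_names_line(tmp_path):
    p = tmp_path / "a.csv"
    p.write_text("t,m\n0.00,1\n0.05,oops\n")
    with pytest.raises(ParseError, match="line 3"):
        read_accel_csv(p)


def test_accel_csv_magnitude_round_trip(tmp_path):
    series = AccelSeries(sampling_rate=20, samples=np.linspace(0.9, 1.1, 40))
    p = tmp_path / "m.csv"
    write_accel_csv(series, p)
    back = read_accel_csv(p, sampling_rate=20)
    assert np.allclose(back.samples, series.samples, atol=1e-6)


def test_daily_csv_two_rows(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("date,steps\n2021-01-01,5000\n2021-01-02,6000\n")
    out = read_daily_csv(p, device="reference")
    assert [(s.day_id, s.steps) for s in out] == [("2021-01-01", 5000), ("2021-01-02", 6000)]


def test_daily_csv_negative_steps_rejected(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("date,steps\n2021-01-01,-1\n")
    with pytest.raises(ValidationError):
        read_daily_csv(p, device="reference")


def test_daily_csv_duplicate_date_rejected(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text("date,steps\n2021-01-01,100\n2021-01-01,200\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_daily_csv(p, device="reference")


@given(
    st.lists(
        st.tuples(st.integers(0, 40000), st.integers(0, 1440)),
        min_size=1,
        max_size=30,
    )
)
def test_daily_csv_round_trip_identity(tmp_path_factory, rows):
    tmp = tmp_path_factory.mktemp("rt")
    summaries = [
        DailySummary(day_id=f"2021-{1 + i // 28:02d}-{1 + i % 28:02d}", device="watch", steps=s, wear_minutes=w)
        for i, (s, w) in enumerate(rows)
    ]
    p = tmp / "d.csv"
    write_daily_csv(summaries, p)
    assert read_daily_csv(p, device="watch") == summaries


def test_write_daily_csv_empty_rejected(tmp_path):
    with pytest.raises(ValidationError):
        write_daily_csv([], tmp_path / "d.csv")


def test_wear_minutes_beyond_day_rejected():
    with pytest.raises(ValidationError):
        DailySummary(day_id="2021-01-01", device="watch", steps=0, wear_minutes=1500)


def test_wear_csv_parses_flags(tmp_path):
    p = tmp_path / "w.csv"
    p.write_text("date,hour,worn\n2021-01-01,0,1\n2021-01-01,1,0\n")
    flags = read_wear_csv(p)
    assert flags == {"2021-01-01": {0: True, 1: False}}


def test_accel_series_wear_flags_must_cover_span():
    with pytest.raises(ValidationError, match="wear_flags"):
        AccelSeries(sampling_rate=20, samples=np.ones(20 * 7200), wear_flags={0: True})


def test_step_config_candidates_must_increase():
    with pytest.raises(ValidationError):
        StepConfig(candidate_thresholds=(0.1, 0.1))


def test_low_window_with_steps_is_invalid():
    from wriststep import ActivityLevel, WindowResult

    with pytest.raises(ValidationError):
        WindowResult(window_index=0, activity=ActivityLevel.LOW, steps=3)
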