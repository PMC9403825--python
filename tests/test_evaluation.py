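"""Agreement-protocol statistics: wear filter, % difference, OLS, Bland-Altman."""

import math

import numpy as np
import pytest
from scipy import stats

from wriststep import (
    DailySummary,
    ValidationError,
    WearCriteria,
    bland_altman,
    error_rate_vs_truth,
    evaluate_agreement,
    filter_worn_days,
    fit_regression,
    pct_diff,
)


def _watch(day, steps, wear):
    return DailySummary(day_id=day, device="watch", steps=steps, wear_minutes=wear)


def _ref(day, steps):
    return DailySummary(day_id=day, device="reference", steps=steps)


def test_wear_threshold_constant():
    assert WearCriteria().wear_minutes_threshold == 675.0


@pytest.mark.parametrize(
    "wear, ref_steps, kept",
    [
        (675, 101, True),   # watch boundary inclusive, reference strict
        (675, 100, False),  # reference exactly at minimum is dropped
        (674, 5000, False),
        (600, 5000, False),
        (1440, 12000, True),
    ],
)
def test_wear_filter_boundaries(wear, ref_steps, kept):
    pairs = filter_worn_days([_watch("2021-01-01", 1000, wear)], [_ref("2021-01-01", ref_steps)])
    assert (len(pairs) == 1) == kept


def test_wear_filter_subset_of_date_intersection_and_order_independent(rng):
    watch = [_watch(f"2021-01-{d:02d}", int(rng.integers(0, 9000)), int(rng.integers(0, 1440))) for d in range(1, 20)]
    ref = [_ref(f"2021-01-{d:02d}", int(rng.integers(0, 9000))) for d in range(5, 28)]
    pairs = filter_worn_days(watch, ref)
    inter = {w.day_id for w in watch} & {r.day_id for r in ref}
    assert all(w.day_id in inter and w.day_id == r.day_id for w, r in pairs)
    shuffled = filter_worn_days(list(reversed(watch)), list(reversed(ref)))
    assert shuffled == pairs


@pytest.mark.parametrize("w, r, expected", [(97, 100, -3.0), (100, 100, 0.0), (110, 100, 10.0), (45, 50, -10.0)])
def test_pct_diff_values(w, r, expected):
    assert pct_diff(w, r) == pytest.approx(expected)
    assert error_rate_vs_truth(w, r) == pytest.approx(expected)


def test_pct_diff_zero_reference_rejected():
    with pytest.raises(ValidationError):
        pct_diff(100, 0)


def test_regression_exact_line():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    slope, intercept, r2 = fit_regression(x, 2 * x + 1)
    assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))


def test_regression_r2_equals_squared_pearson(rng):
    for _ in range(20):
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        _, _, r2 = fit_regression(x, y)
        assert r2 == pytest.approx(stats.pearsonr(x, y)[0] ** 2, abs=1e-10)


def test_regression_independent_y_r2_near_zero(rng):
    x = rng.normal(0, 1, 5000)
    y = rng.normal(0, 1, 5000)
    _, _, r2 = fit_regression(x, y)
    assert r2 < 0.01


def test_regression_degenerate_inputs():
    with pytest.raises(ValidationError):
        fit_regression([1, 2], [1, 2])
    with pytest.raises(ValidationError):
        fit_regression([3, 3, 3], [1, 2, 3])


def test_bland_altman_identical_series():
    mean, up, lo, out = bland_altman([(100, 100), (200, 200), (300, 300)])
    assert (mean, up, lo) == (0.0, 0.0, 0.0)
    assert out == []


def test_bland_altman_plus_minus_one():
    """Differences {+1, -1}: mean 0, sample SD sqrt(2), limits ±2·sqrt(2)."""
    mean, up, lo, out = bland_altman([(101, 100), (99, 100)])
    assert mean == pytest.approx(0.0)
    assert up == pytest.approx(2 * math.sqrt(2))
    assert lo == pytest.approx(-2 * math.sqrt(2))
    assert out == []


def test_bland_altman_single_pair_rejected():
    with pytest.raises(ValidationError):
        bland_altman([(100, 100)])


def test_bland_altman_gaussian_coverage(rng):
    """±2 SD limits cover about 95.4% of Gaussian differences."""
    d = rng.normal(0, 300, 100_000)
    pairs = [(float(v), 0.0) for v in d]
    mean, up, lo, out = bland_altman(pairs)
    coverage = 1 - len(out) / len(pairs)
    assert coverage == pytest.approx(0.9545, abs=0.005)


def test_evaluate_agreement_end_to_end(rng):
    days = [f"2021-01-{d:02d}" for d in range(1, 21)]
    ref_steps = rng.integers(2000, 12000, 20)
    watch, ref = [], []
    for day, r in zip(days, ref_steps):
        w = int(r * (1 + rng.normal(0.02, 0.05)))
        watch.append(_watch(day, w, 900))
        ref.append(_ref(day, int(r)))
    report = evaluate_agreement(watch, ref)
    assert report.n_days == 20
    assert report.ba_lower <= report.ba_mean_diff <= report.ba_upper
    assert 0 <= report.r2 <= 1
    assert report.r2 > 0.9  # watch tracks reference by construction
    doc = report.to_json()
    assert '"n_days": 20' in doc
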