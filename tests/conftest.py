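import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibrated():
    """Simulator-calibrated default config, gate model and report."""
    from wriststep import calibrate_defaults

    return calibrate_defaults(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# --- independent brute-force oracles (naive loop re-implementations) ---


def naive_zero_mean(x, history):
    x = list(map(float, x))
    out = []
    for i in range(len(x)):
        if i == 0:
            out.append(0.0)
            continue
        lo = max(0, i - history)
        prev = x[lo:i]
        out.append(x[i] - sum(prev) / len(prev))
    return out


def naive_moving_average(x, length):
    x = list(map(float, x))
    out = []
    for i in range(len(x)):
        if i == 0:
            out.append(x[0])
            continue
        lo = max(0, i - length)
        prev = x[lo:i]
        out.append(sum(prev) / len(prev))
    return out


def oracle_peaks(v, threshold):
    """Collapse plateaus to their first sample, then strict local maxima above threshold."""
    v = list(map(float, v))
    idx, vals = [], []
    for i, val in enumerate(v):
        if not vals or val != vals[-1]:
            idx.append(i)
            vals.append(val)
    peaks = []
    for k in range(1, len(vals) - 1):
        if vals[k - 1] < vals[k] > vals[k + 1] and vals[k] > threshold:
            peaks.append(idx[k])
    return peaks


@pytest.fixture(scope="session")
def oracles():
    return naive_zero_mean, naive_moving_average, oracle_peaks
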