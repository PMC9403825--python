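"""Window features, gate models, and the LOSO cross-validation harness."""

import numpy as np
import pytest

from wriststep import ActivityLevel, ValidationError, classify_activity, extract_features, loso_cv, train_activity_model
from wriststep.activity_gate import FEATURE_NAMES, ActivityModel, load_model, save_model


def test_constant_window_features():
    f = extract_features(np.full(100, 1.0))
    named = dict(zip(FEATURE_NAMES, f))
    assert named["mean_m"] == 1.0
    assert named["sd_m"] == 0.0
    assert named["range_m"] == 0.0


def test_alternating_window_sample_sd():
    f = extract_features(np.array([0.0, 2.0, 0.0, 2.0]))
    assert dict(zip(FEATURE_NAMES, f))["sd_m"] == pytest.approx(1.1547, abs=1e-4)


def test_features_deterministic():
    w = np.random.default_rng(0).normal(1, 0.1, 100)
    assert np.array_equal(extract_features(w), extract_features(w))


def test_empty_window_rejected():
    with pytest.raises(ValidationError):
        extract_features(np.array([]))


def _clusters(rng, n_per=40):
    """Three well-separated Gaussian clusters in feature space."""
    X, y, subj = [], [], []
    centers = {"low": 0.01, "moderate": 0.10, "vigorous": 0.25}
    for ci, (label, sd_level) in enumerate(centers.items()):
        for i in range(n_per):
            w = rng.normal(1.0, sd_level, 100)
            X.append(extract_features(w))
            y.append(label)
            subj.append(i % 5)
    return np.array(X), np.array(y), np.array(subj)


@pytest.mark.parametrize("kind", ["linear_margin", "sd_threshold"])
def test_separable_clusters_train_to_full_accuracy(kind, rng):
    X, y, _ = _clusters(rng)
    model = train_activity_model(X, y, kind=kind, seed=0)
    preds = [classify_activity(x, model).value for x in X]
    assert np.mean(np.array(preds) == y) == 1.0


def test_single_class_training_rejected(rng):
    X, y, _ = _clusters(rng)
    with pytest.raises(ValidationError):
        train_activity_model(X[y == "low"], y[y == "low"])


def test_too_few_examples_per_class_rejected(rng):
    X, y, _ = _clusters(rng, n_per=4)
    with pytest.raises(ValidationError):
        train_activity_model(X, y)


def test_classification_is_deterministic(rng):
    X, y, _ = _clusters(rng)
    model = train_activity_model(X, y, seed=0)
    assert classify_activity(X[0], model) == classify_activity(X[0], model)


def test_unfitted_model_rejected():
    model = ActivityModel(kind="sd_threshold")
    with pytest.raises(ValidationError, match="not fitted"):
        classify_activity(np.zeros(7), model)


def test_sd_threshold_rest_is_low():
    model = ActivityModel(kind="sd_threshold", cutoffs=(0.05, 0.15))
    f = extract_features(np.zeros(100))
    assert classify_activity(f, model) is ActivityLevel.LOW


def test_loso_separable_accuracy_high(rng):
    X, y, subj = _clusters(rng)
    assert loso_cv(X, y, subj, kind="linear_margin") >= 0.95


def test_loso_permuted_labels_near_chance(rng):
    X, _, subj = _clusters(rng, n_per=60)
    y_perm = rng.permutation(np.repeat(["low", "moderate", "vigorous"], 60))
    acc = loso_cv(X, y_perm, subj, kind="linear_margin")
    assert abs(acc - 1 / 3) < 0.12  # Monte-Carlo tolerance, 3 balanced classes


def test_loso_single_subject_rejected(rng):
    X, y, _ = _clusters(rng)
    with pytest.raises(ValidationError):
        loso_cv(X, y, np.zeros(len(y)))


@pytest.mark.parametrize("kind", ["linear_margin", "sd_threshold"])
def test_yaml_round_trip_preserves_predictions(kind, rng, tmp_path):
    X, y, _ = _clusters(rng)
    model = train_activity_model(X, y, kind=kind, seed=0)
    path = tmp_path / "model.yaml"
    save_model(model, path)
    back = load_model(path)
    preds_a = [classify_activity(x, model) for x in X]
    preds_b = [classify_activity(x, back) for x in X]
    assert preds_a == preds_b


def test_simulator_confounders_labeled_low(calibrated):
    """Non-wear and random-hand-motion windows are low in >= 95% of cases."""
    from wriststep import GaitScenario, segment_windows, simulate_bout

    _, gate, _ = calibrated
    for pattern in ("nonwear", "hand_motion", "rest"):
        series, _ = simulate_bout(GaitScenario(pattern=pattern, duration=300, seed=11))
        labels = [
            classify_activity(extract_features(w), gate)
            for w in segment_windows(series.samples, series.sampling_rate, 5.0)
        ]
        frac_low = np.mean([lv is ActivityLevel.LOW for lv in labels])
        assert frac_low >= 0.95, pattern
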