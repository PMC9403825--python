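"""Activity-level classification gating the step counter.

Each 5-second window of raw magnitude is labeled low / moderate /
vigorous; only moderate and vigorous windows are passed to peak
counting.  This two-phase design exists to stop random hand motion,
desk work and other non-locomotor movement from registering as steps.

Two interchangeable model kinds are provided:

* ``sd_threshold`` — the default gate: a window is moderate when the
  sample SD of its magnitude exceeds a calibrated cut-off and vigorous
  above a second cut-off.  It needs no training data and its two
  numbers are set by the simulator calibration routine.
* ``linear_margin`` — a linear max-margin classifier (one-vs-rest) over
  seven time-domain features, standardized; trained with
  scikit-learn but predicted from its stored weights so serialized
  models are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .types import ActivityLevel, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "ActivityModel",
    "train_activity_model",
    "classify_activity",
    "loso_cv",
    "save_model",
    "load_model",
]

FEATURE_NAMES = ("mean_m", "sd_m", "min_m", "max_m", "energy", "zero_crossings", "range_m")

_LEVELS = (ActivityLevel.LOW, ActivityLevel.MODERATE, ActivityLevel.VIGOROUS)


def extract_features(window: np.ndarray) -> np.ndarray:
    """Seven time-domain features of a raw magnitude window.

    mean, sample SD, min, max, energy (mean squared deviation from the
    window mean, in g²), zero crossings of the mean-removed signal, and
    range.  Deterministic and cheap enough for on-device use.
    """
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValidationError("cannot extract features from an empty window")
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1)) if w.size > 1 else 0.0
    centered = w - mean
    energy = float(np.mean(centered**2))
    # count sign alternations of the centered signal; zeros do not alternate
    s = np.sign(centered)
    s = s[s != 0]
    crossings = int(np.sum(s[:-1] != s[1:])) if s.size > 1 else 0
    return np.array([mean, sd, float(np.min(w)), float(np.max(w)), energy, crossings, float(np.ptp(w))])


@dataclass
class ActivityModel:
    """A fitted window classifier.

    ``sd_threshold``: uses ``cutoffs = (moderate, vigorous)`` on the
    ``sd_m`` feature.  ``linear_margin``: one-vs-rest linear scores
    ``W @ z + b`` over standardized features ``z = (x - mu) / sigma``;
    the argmax class wins.
    """

    kind: str
    classes: tuple[str, ...] = tuple(lv.value for lv in _LEVELS)
    cutoffs: tuple[float, float] | None = None
    weights: np.ndarray | None = None
    biases: np.ndarray | None = None
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    schema: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("sd_threshold", "linear_margin"):
            raise ValidationError(f"unknown model kind {self.kind!r}")

    @property
    def fitted(self) -> bool:
        if self.kind == "sd_threshold":
            return self.cutoffs is not None
        return self.weights is not None


def train_activity_model(
    features: np.ndarray,
    labels: Sequence[ActivityLevel | str],
    kind: str = "linear_margin",
    seed: int = 0,
) -> ActivityModel:
    """Fit an activity classifier on labeled window features.

    Requires at least two classes and five examples per class.  For
    ``sd_threshold`` the cut-offs are midpoints between the per-class
    mean ``sd_m`` values; for ``linear_margin`` a linear SVM is fitted
    on standardized features.
    """
    X = np.asarray(features, dtype=float)
    y = np.array([ActivityLevel(l).value for l in labels])
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError("features must be (n_windows, n_features) matching labels")
    present = [lv.value for lv in _LEVELS if lv.value in set(y)]
    if len(present) < 2:
        raise ValidationError("training needs at least 2 classes")
    counts = {c: int(np.sum(y == c)) for c in present}
    if min(counts.values()) < 5:
        raise ValidationError(f"need >= 5 examples per class, got {counts}")

    if kind == "sd_threshold":
        sd_col = FEATURE_NAMES.index("sd_m")
        means = {c: float(np.mean(X[y == c, sd_col])) for c in present}
        order = sorted(present, key=lambda c: means[c])
        mids = [(means[a] + means[b]) / 2 for a, b in zip(order, order[1:])]
        mod = mids[0]
        vig = mids[1] if len(mids) > 1 else float("inf")
        return ActivityModel(kind="sd_threshold", cutoffs=(mod, vig))

    if kind == "linear_margin":
        from sklearn.svm import LinearSVC

        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        sigma[sigma == 0] = 1.0
        Z = (X - mu) / sigma
        clf = LinearSVC(C=1.0, random_state=seed, max_iter=20000)
        clf.fit(Z, y)
        classes = tuple(str(c) for c in clf.classes_)
        coef = np.atleast_2d(clf.coef_)
        intercept = np.atleast_1d(clf.intercept_)
        if len(classes) == 2:  # expand binary decision into two-row ovr form
            coef = np.vstack([-coef[0], coef[0]])
            intercept = np.array([-intercept[0], intercept[0]])
        return ActivityModel(
            kind="linear_margin",
            classes=classes,
            weights=coef,
            biases=intercept,
            scale_mean=mu,
            scale_sd=sigma,
        )

    raise ValidationError(f"unknown model kind {kind!r}")


def classify_activity(features: np.ndarray, model: ActivityModel) -> ActivityLevel:
    """Deterministically label one window's feature vector."""
    if not model.fitted:
        raise ValidationError("model is not fitted")
    x = np.asarray(features, dtype=float)
    if model.kind == "sd_threshold":
        sd = x[FEATURE_NAMES.index("sd_m")]
        mod, vig = model.cutoffs
        if sd > vig:
            return ActivityLevel.VIGOROUS
        if sd > mod:
            return ActivityLevel.MODERATE
        return ActivityLevel.LOW
    z = (x - model.scale_mean) / model.scale_sd
    scores = model.weights @ z + model.biases
    return ActivityLevel(model.classes[int(np.argmax(scores))])


def loso_cv(
    features: np.ndarray,
    labels: Sequence[ActivityLevel | str],
    subjects: Sequence[object],
    kind: str = "linear_margin",
    seed: int = 0,
) -> float:
    """Leave-one-subject-out cross-validated window accuracy, in [0, 1].

    Each subject's windows are held out in turn; the model is refit on
    the rest and scored on the held-out windows.  The returned value is
    the pooled per-window accuracy.
    """
    X = np.asarray(features, dtype=float)
    y = np.array([ActivityLevel(l).value for l in labels])
    subj = np.asarray(subjects)
    uniq = np.unique(subj)
    if uniq.size < 2:
        raise ValidationError("LOSO cross-validation needs at least 2 subjects")
    correct = 0
    for held in uniq:
        mask = subj == held
        model = train_activity_model(X[~mask], y[~mask], kind=kind, seed=seed)
        preds = [classify_activity(row, model).value for row in X[mask]]
        correct += int(np.sum(np.array(preds) == y[mask]))
    return correct / y.size


def save_model(model: ActivityModel, path: str | Path) -> None:
    """Serialize a model to a flat YAML document (schema-versioned)."""
    doc: dict = {"schema": model.schema, "kind": model.kind, "classes": list(model.classes)}
    if model.kind == "sd_threshold":
        doc["cutoffs"] = [float(c) for c in model.cutoffs]
    else:
        doc["weights"] = model.weights.tolist()
        doc["biases"] = model.biases.tolist()
        doc["scale_mean"] = model.scale_mean.tolist()
        doc["scale_sd"] = model.scale_sd.tolist()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: str | Path) -> ActivityModel:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("schema") != 1:
        raise ValidationError(f"unsupported model schema {doc.get('schema')!r}")
    kind = doc["kind"]
    if kind == "sd_threshold":
        return ActivityModel(kind=kind, classes=tuple(doc["classes"]), cutoffs=tuple(doc["cutoffs"]))
    return ActivityModel(
        kind=kind,
        classes=tuple(doc["classes"]),
        weights=np.asarray(doc["weights"], dtype=float),
        biases=np.asarray(doc["biases"], dtype=float),
        scale_mean=np.asarray(doc["scale_mean"], dtype=float),
        scale_sd=np.asarray(doc["scale_sd"], dtype=float),
    )
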