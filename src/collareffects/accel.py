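"""Tri-axial accelerometer features, behavior classification, and
hourly headshake aggregation.

Raw 8 Hz x/y/z streams (surge, sway, heave) are decomposed into static
(postural) and dynamic (movement) acceleration with a 2-second moving
window, summarized as 13 per-record predictors (static, dynamic,
running min/max per axis, plus VeDBA), classified with a random forest,
and the classified headshake records aggregated into hourly binomial
counts for the time-series models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

__all__ = [
    "BEHAVIORS",
    "FEATURE_COLUMNS",
    "ClassifierReport",
    "static_acceleration",
    "dynamic_acceleration",
    "vedba",
    "running_minmax",
    "build_features",
    "build_training_set",
    "train_classifier",
    "evaluate_classifier",
    "aggregate_hourly",
]

BEHAVIORS = ("rest", "feed", "locomote", "headshake")

AXES = ("x", "y", "z")

FEATURE_COLUMNS = (
    [f"static_{ax}" for ax in AXES]
    + [f"dynamic_{ax}" for ax in AXES]
    + [f"runmin_{ax}" for ax in AXES]
    + [f"runmax_{ax}" for ax in AXES]
    + ["vedba"]
)

#: Clock hours treated as daytime (pasture) by default: [08:00, 17:00).
DAY_HOURS = (8, 17)


def _window_bounds(n: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered window [i - w//2, i + (w+1)//2), clipped at the edges.

    Interior windows contain exactly ``window`` samples; edge windows
    shrink.
    """
    idx = np.arange(n)
    lo = np.maximum(idx - window // 2, 0)
    hi = np.minimum(idx + (window + 1) // 2, n)
    return lo, hi


def _window_samples(window_s: float, rate_hz: float) -> int:
    w = int(round(window_s * rate_hz))
    if w < 1:
        raise ValueError("window shorter than one sample")
    return w


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    n = x.size
    lo, hi = _window_bounds(n, window)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    return (csum[hi] - csum[lo]) / (hi - lo)


def _moving_extreme(x: np.ndarray, window: int, mode: str) -> np.ndarray:
    n = x.size
    out = np.empty(n)
    fn = np.min if mode == "min" else np.max
    lo, hi = _window_bounds(n, window)
    full = (hi - lo) == window
    if full.any():
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        out[full] = fn(sw[lo[full]], axis=1)
    for i in np.nonzero(~full)[0]:  # shrunken edge windows
        out[i] = fn(x[lo[i] : hi[i]])
    return out


def _stream_axes(stream: pd.DataFrame) -> np.ndarray:
    cols = [f"a{ax}" for ax in AXES]
    missing = set(cols) - set(stream.columns)
    if missing:
        raise ValueError(f"stream missing columns: {sorted(missing)}")
    if len(stream) == 0:
        raise ValueError("empty stream")
    arr = stream[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite acceleration values")
    return arr


def static_acceleration(
    stream: pd.DataFrame, window_s: float = 2.0, rate_hz: float = 8.0
) -> pd.DataFrame:
    """Per-axis centered moving average (gravitational component).

    2 s at 8 Hz gives a 16-sample window; edge windows shrink.
    """
    arr = _stream_axes(stream)
    w = _window_samples(window_s, rate_hz)
    out = {f"static_{ax}": _moving_mean(arr[:, j], w) for j, ax in enumerate(AXES)}
    return pd.DataFrame(out, index=stream.index)


def dynamic_acceleration(raw: pd.DataFrame, static: pd.DataFrame) -> pd.DataFrame:
    """Movement component: raw minus static, elementwise and exact."""
    if len(raw) != len(static):
        raise ValueError("raw and static lengths differ")
    out = {}
    for ax in AXES:
        out[f"dynamic_{ax}"] = (
            raw[f"a{ax}"].to_numpy(dtype=float)
            - static[f"static_{ax}"].to_numpy(dtype=float)
        )
    return pd.DataFrame(out, index=raw.index)


def vedba(dynamic: pd.DataFrame) -> np.ndarray:
    """Vectorial dynamic body acceleration: sqrt(dx^2 + dy^2 + dz^2)."""
    dx = dynamic["dynamic_x"].to_numpy(dtype=float)
    dy = dynamic["dynamic_y"].to_numpy(dtype=float)
    dz = dynamic["dynamic_z"].to_numpy(dtype=float)
    if not (dx.size == dy.size == dz.size):
        raise ValueError("axis length mismatch")
    return np.sqrt(dx * dx + dy * dy + dz * dz)


def running_minmax(
    stream: pd.DataFrame, window_s: float = 2.0, rate_hz: float = 8.0
) -> pd.DataFrame:
    """Centered running min and max per axis, same window as static."""
    arr = _stream_axes(stream)
    w = _window_samples(window_s, rate_hz)
    out = {}
    for j, ax in enumerate(AXES):
        out[f"runmin_{ax}"] = _moving_extreme(arr[:, j], w, "min")
        out[f"runmax_{ax}"] = _moving_extreme(arr[:, j], w, "max")
    return pd.DataFrame(out, index=stream.index)


def build_features(
    stream: pd.DataFrame, window_s: float = 2.0, rate_hz: float = 8.0
) -> pd.DataFrame:
    """Assemble the 13 per-record predictors for classification."""
    static = static_acceleration(stream, window_s, rate_hz)
    dyn = dynamic_acceleration(stream, static)
    mm = running_minmax(stream, window_s, rate_hz)
    feats = pd.concat([static, dyn, mm], axis=1)
    feats["vedba"] = vedba(dyn)
    return feats[list(FEATURE_COLUMNS)]


def build_training_set(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int,
    per_class_records: int = 2400,
    rare_fraction: float = 1.0 / 3.0,
    rare_classes: tuple[str, ...] = ("headshake",),
) -> tuple[np.ndarray, np.ndarray]:
    """Indices for a training/validation split mirroring the study design.

    Common behaviors contribute ``per_class_records`` records each
    (5 min at 8 Hz = 2,400); rare classes contribute roughly a third of
    their records.  Returns (train_idx, test_idx); the remainder of
    every class goes to the test set.
    """
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("features and labels lengths differ")
    rng = np.random.default_rng(seed)
    train_parts = []
    test_parts = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        if cls in rare_classes:
            k = max(1, int(round(len(idx) * rare_fraction)))
        else:
            k = min(per_class_records, len(idx) - 1) if len(idx) > 1 else 1
        train_parts.append(idx[:k])
        test_parts.append(idx[k:])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return train_idx, test_idx


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int,
    n_estimators: int = 500,
    **rf_kwargs,
) -> RandomForestClassifier:
    """Fit a random forest (500 trees, sqrt-p splits, unlimited depth)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
        **rf_kwargs,
    )
    clf.fit(features.to_numpy(dtype=float), y)
    return clf


@dataclass
class ClassifierReport:
    """One-vs-rest metrics per behavior plus the confusion matrix.

    ``accuracy`` per behavior is (TP+TN)/total — the proportion of
    records correctly classified either way for that behavior.
    """

    classes: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    accuracy: dict[str, float]
    overall_accuracy: float
    confusion: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "behavior": self.classes,
                "precision": [self.precision[c] for c in self.classes],
                "recall": [self.recall[c] for c in self.classes],
                "accuracy": [self.accuracy[c] for c in self.classes],
            }
        )


def evaluate_classifier(
    predictions: np.ndarray | pd.Series, truth: np.ndarray | pd.Series
) -> ClassifierReport:
    """Per-behavior precision, recall and accuracy plus overall accuracy.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    accuracy = (TP+TN)/total; overall accuracy = trace/total.
    """
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.size != true.size:
        raise ValueError("predictions and truth lengths differ")
    if pred.size == 0:
        raise ValueError("empty input")
    classes = sorted(set(true) | set(pred))
    cm = confusion_matrix(true, pred, labels=classes).astype(float)
    total = cm.sum()
    precision, recall, accuracy = {}, {}, {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = total - tp - fp - fn
        precision[cls] = tp / (tp + fp) if tp + fp > 0 else float("nan")
        recall[cls] = tp / (tp + fn) if tp + fn > 0 else float("nan")
        accuracy[cls] = (tp + tn) / total
    return ClassifierReport(
        classes=classes,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        overall_accuracy=float(np.trace(cm) / total),
        confusion=pd.DataFrame(cm.astype(int), index=classes, columns=classes),
    )


def aggregate_hourly(
    classified: pd.DataFrame,
    collar_time: object,
    day_hours: tuple[int, int] = DAY_HOURS,
    headshake_label: str = "headshake",
) -> pd.DataFrame:
    """Hourly binomial headshake counts since collar fitting.

    Hours are half-open intervals [t, t+1) measured from
    ``collar_time``; a partial trailing hour keeps its true trial
    count.  The day flag comes from the clock hour at the start of each
    interval: [day_hours[0], day_hours[1]) is daytime.

    Returns a frame with columns ``t_hours``, ``y``, ``N``, ``is_day``.
    """
    if "timestamp" not in classified.columns or "label" not in classified.columns:
        raise ValueError("classified stream needs 'timestamp' and 'label' columns")
    ts = pd.to_datetime(classified["timestamp"])
    origin = pd.to_datetime(collar_time)
    rel_s = (ts - origin).dt.total_seconds().to_numpy()
    if np.any(rel_s < 0):
        raise ValueError("records before collar_time")
    hour = np.floor(rel_s / 3600.0).astype(int)
    is_hs = (classified["label"] == headshake_label).to_numpy()

    df = pd.DataFrame({"t_hours": hour, "hs": is_hs})
    g = df.groupby("t_hours", sort=True)
    out = g["hs"].agg(y="sum", N="count").reset_index()
    clock = (origin.hour + out["t_hours"] + origin.minute / 60.0) % 24
    clock_h = np.floor(clock).astype(int)
    out["is_day"] = (clock_h >= day_hours[0]) & (clock_h < day_hours[1])
    out["y"] = out["y"].astype(int)
    out["N"] = out["N"].astype(int)
    return out[["t_hours", "y", "N", "is_day"]]
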