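"""Sliding-window feature extraction and expression classification.

From each window of ``R`` samples of a source channel (synergy activation
coefficient or sEMG envelope) four standard amplitude features are
computed::

    RMS  = sqrt(mean(x^2))          VAR  = mean((x - mean(x))^2)
    MAV  = mean(|x|)                IEMG = sum(|x|)

Windows are label-pure: they never straddle a segment boundary (transition
samples were already trimmed), and each window inherits its segment's
expression label.  The default window is R = 125 samples at 1024 Hz with a
40 ms step (one video frame).  A random forest (100 trees, otherwise
default parameters) classifies windows into neutral + six expressions; the
identical code path serves synergy-activation features (s x 4 columns) and
per-muscle envelope features (7 x 4 columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import cross_val_score

from .core import TrialStructure

WINDOW_SAMPLES = 125   # at 1024 Hz (~122 ms; nominal 150 ms window)
STEP_S = 0.040
FEATURES = ("rms", "var", "mav", "iemg")


@dataclass
class FeatureTable:
    """Windowed features: one row per window, 4 features per source channel."""

    X: np.ndarray                       # n_windows x (4 * n_channels)
    labels: np.ndarray                  # n_windows object array of label strings
    feature_names: list[str]
    t_centers: np.ndarray
    window: int
    step: int

    def __post_init__(self):
        if self.X.shape[0] != len(self.labels):
            raise ValueError("one label per window required")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")

    def __len__(self):
        return self.X.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "t_center_s", self.t_centers)
        return df


def concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    if not tables:
        raise ValueError("nothing to concatenate")
    ref = tables[0]
    for t in tables[1:]:
        if t.feature_names != ref.feature_names:
            raise ValueError("feature schema mismatch")
    return FeatureTable(
        np.concatenate([t.X for t in tables]),
        np.concatenate([t.labels for t in tables]),
        ref.feature_names,
        np.concatenate([t.t_centers for t in tables]),
        ref.window, ref.step,
    )


def window_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(RMS, VAR, MAV, IEMG) of one window; VAR uses 1/R normalization."""
    x = np.asarray(x, dtype=float)
    rms = float(np.sqrt(np.mean(x * x)))
    var = float(np.mean((x - x.mean()) ** 2))
    mav = float(np.mean(np.abs(x)))
    iemg = float(np.sum(np.abs(x)))
    return rms, var, mav, iemg


def sliding_features(X: np.ndarray, structure: TrialStructure, fs: float,
                     channel_names: list[str],
                     window: int = WINDOW_SAMPLES,
                     step: int | None = None) -> FeatureTable:
    """Windowed RMS/VAR/MAV/IEMG features of a channels-by-time matrix.

    ``X`` is either the synergy activation matrix ``C`` or the sEMG envelope
    matrix; windows are placed inside each labelled segment and dropped at
    boundaries.
    """
    X = np.asarray(X, dtype=float)
    if window < 2:
        raise ValueError("window must span at least 2 samples")
    if step is None:
        step = int(round(STEP_S * fs))
    if step < 1:
        raise ValueError("step must be >= 1 sample")
    if X.shape[0] != len(channel_names):
        raise ValueError("channel_names must match rows of X")

    feature_names = [f"{ch}_{f}" for ch in channel_names for f in FEATURES]
    rows, labels, centers = [], [], []
    for seg in structure:
        i0 = int(round(seg.start_s * fs))
        i1 = min(int(round(seg.end_s * fs)), X.shape[1])
        if i1 - i0 < window:
            raise ValueError(
                f"window of {window} samples exceeds segment {seg.label!r} "
                f"(trial {seg.trial}, rep {seg.repetition}: {i1 - i0} samples)")
        for start in range(i0, i1 - window + 1, step):
            w = X[:, start:start + window]
            rows.append(np.concatenate([window_features(w[c])
                                        for c in range(X.shape[0])]))
            labels.append(seg.label)
            centers.append((start + window / 2) / fs)
    return FeatureTable(np.array(rows), np.array(labels, dtype=object),
                        feature_names, np.array(centers), window, step)


def split_train_test(participants: list, n_trials: int = 12, n_train: int = 10,
                     seed: int = 0) -> dict:
    """Per-participant random train/test split of reordered-trial indices.

    Returns ``{participant: (train_indices, test_indices)}`` with ``n_train``
    trials in the training set and the remainder held out; deterministic in
    ``seed``.
    """
    if n_train >= n_trials:
        raise ValueError("n_train must leave at least one test trial")
    rng = np.random.default_rng(seed)
    split = {}
    for p in participants:
        perm = rng.permutation(n_trials)
        split[p] = (tuple(int(i) for i in sorted(perm[:n_train])),
                    tuple(int(i) for i in sorted(perm[n_train:])))
    return split


def segment_majority_vote(y_pred: np.ndarray, t_centers: np.ndarray,
                          structure: TrialStructure) -> np.ndarray:
    """Optional post-step: modal prediction per segment (off by default).

    Window-level metrics are the primary output; this smooths predictions
    by replacing every window's label with the most frequent prediction
    among the windows of its segment.
    """
    out = np.array(y_pred, dtype=object, copy=True)
    for seg in structure:
        mask = (t_centers >= seg.start_s) & (t_centers < seg.end_s)
        if np.any(mask):
            labels, counts = np.unique(out[mask].astype(str),
                                       return_counts=True)
            out[mask] = labels[np.argmax(counts)]
    return out


@dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    feature_names: list[str]
    classes: list[str]
    cv_accuracy: float | None = None
    cv_scores: np.ndarray | None = None


def train_classifier(features: FeatureTable, n_trees: int = 100,
                     cv_folds: int = 5, seed: int = 0) -> TrainedClassifier:
    """Random forest on window features, with k-fold CV accuracy on train."""
    classes = sorted(set(features.labels))
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    cv_scores = None
    cv_acc = None
    if cv_folds and cv_folds > 1:
        cv_scores = cross_val_score(model, features.X, features.labels,
                                    cv=cv_folds, scoring="accuracy")
        cv_acc = float(np.mean(cv_scores))
    model.fit(features.X, features.labels)
    return TrainedClassifier(model, features.feature_names, classes,
                             cv_acc, cv_scores)


@dataclass
class ClassifierReport:
    accuracy: float                          # percent
    per_class_accuracy: dict[str, float]     # percent, recall per true class
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    auc: dict[str, float]
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False,
                                                                 default_factory=dict)
    confusion: pd.DataFrame | None = None    # true rows x predicted columns

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion_matrix": None if self.confusion is None
            else self.confusion.to_dict(),
        }


def evaluate_classifier(clf: TrainedClassifier, test: FeatureTable) -> ClassifierReport:
    """Window-level metrics on a held-out feature table."""
    if test.feature_names != clf.feature_names:
        raise ValueError("feature schema differs from training")
    y_true = test.labels
    y_pred = clf.model.predict(test.X)
    proba = clf.model.predict_proba(test.X)
    model_classes = list(clf.model.classes_)
    classes = sorted(set(model_classes) | set(y_true))

    cm = confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0)

    per_class_acc, auc, curves = {}, {}, {}
    for i, c in enumerate(classes):
        support = cm[i].sum()
        per_class_acc[c] = 100.0 * cm[i, i] / support if support else float("nan")
        if c in model_classes and support and support < len(y_true):
            score = proba[:, model_classes.index(c)]
            y_bin = (y_true == c).astype(int)
            auc[c] = float(roc_auc_score(y_bin, score))
            fpr, tpr, _ = roc_curve(y_bin, score)
            curves[c] = (fpr, tpr)
    return ClassifierReport(
        accuracy=float(accuracy),
        per_class_accuracy=per_class_acc,
        precision={c: float(v) for c, v in zip(classes, prec)},
        recall={c: float(v) for c, v in zip(classes, rec)},
        f1={c: float(v) for c, v in zip(classes, f1)},
        auc=auc,
        roc_curves=curves,
        confusion=pd.DataFrame(cm, index=classes, columns=classes),
    )
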