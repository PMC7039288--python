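"""Activity-intensity classification from tri-axial accelerometry.

A 30-s acceleration window is reduced to six features — the per-axis minima
and maxima in milli-g — and classified into an ordinal five-level intensity
scale (1 sitting, 2 walking, 3 stair climbing, 4 jogging, 5 sprinting) with
a linear one-vs-one multiclass SVM on standardized features.  The per-axis
acceleration ranges characteristic of each level are kept in
:data:`TABLE1_RANGES_MG`.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .types import AccelWindow, ClassifierReport, FeatureVector

__all__ = [
    "TABLE1_RANGES_MG",
    "INTENSITY_LEVELS",
    "extract_features",
    "IntensityClassifier",
    "train_intensity_classifier",
    "classify",
]

#: Reference per-axis acceleration ranges (min, max) in mg for each
#: intensity level, measured over representative activities with the device
#: worn on the upper arm (x medial/lateral, y anterior/posterior,
#: z superior/inferior).
TABLE1_RANGES_MG: dict[int, dict[str, tuple[float, float]]] = {
    1: {"x": (-7.0, 1035.0), "y": (-89.0, 1035.0), "z": (-312.0, -7.0)},
    2: {"x": (-7.0, 1640.0), "y": (-480.0, 753.0), "z": (-1093.0, 160.0)},
    3: {"x": (-7.0, 1925.0), "y": (-265.0, 734.0), "z": (-511.0, 363.0)},
    4: {"x": (-656.0, 1988.0), "y": (-1125.0, 1988.0), "z": (-1390.0, 722.0)},
    5: {"x": (-796.0, 1988.0), "y": (-1980.0, 1984.0), "z": (-1562.0, 1906.0)},
}

INTENSITY_LEVELS = (1, 2, 3, 4, 5)


def extract_features(window: AccelWindow) -> FeatureVector:
    """Six min/max features of a tri-axial window, exact and unsmoothed.

    The features are order-independent: any permutation of the samples
    yields the same vector.
    """
    if window.x.size == 0:
        raise ValueError("cannot extract features from an empty window")
    return FeatureVector(
        x_min=float(window.x.min()),
        x_max=float(window.x.max()),
        y_min=float(window.y.min()),
        y_max=float(window.y.max()),
        z_min=float(window.z.min()),
        z_max=float(window.z.max()),
    )


class IntensityClassifier(ClassifierMixin, BaseEstimator):
    """Activity-intensity classifier: standardized features + linear
    one-vs-one multiclass SVM.

    Features are z-scored with statistics from the training data (axis
    ranges differ by roughly 3x, so unscaled margins would be
    scale-dependent), then passed to an SVM with a linear kernel and
    one-vs-one vote aggregation.  Prediction runs directly off the stored
    linear weights, which makes fitted models serializable as plain JSON.

    Parameters
    ----------
    C : float
        SVM regularization strength (default 1.0).

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen during fit.
    coef_ : ndarray of shape (n_pairs, 6)
        One-vs-one hyperplane normals in standardized feature space, pairs
        ordered (c0,c1), (c0,c2), ..., (c1,c2), ...
    intercept_ : ndarray of shape (n_pairs,)
    scaler_mean_, scaler_scale_ : ndarray of shape (6,)
        Standardization statistics.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        scaler = StandardScaler().fit(X)
        svm = SVC(kernel="linear", C=self.C).fit(scaler.transform(X), y)
        self.classes_ = svm.classes_
        self.coef_ = svm.coef_.copy()
        self.intercept_ = svm.intercept_.copy()
        self.scaler_mean_ = scaler.mean_.copy()
        self.scaler_scale_ = scaler.scale_.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        """One-vs-one decision values, one column per class pair."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        Xs = (X - self.scaler_mean_) / self.scaler_scale_
        return Xs @ self.coef_.T + self.intercept_

    def predict(self, X):
        """Majority vote over the one-vs-one decisions; ties resolve by the
        summed decision margins, then toward the lower class label."""
        dec = self.decision_function(X)
        n_classes = len(self.classes_)
        votes = np.zeros((dec.shape[0], n_classes))
        margins = np.zeros_like(votes)
        k = 0
        for i in range(n_classes):
            for j in range(i + 1, n_classes):
                d = dec[:, k]
                votes[:, i] += d > 0
                votes[:, j] += d <= 0
                margins[:, i] += d
                margins[:, j] -= d
                k += 1
        # bounded margin tweak (same trick sklearn uses) so that vote ties
        # break by confidence without ever overturning a vote difference
        score = votes + margins / (3.0 * (np.abs(margins) + 1.0))
        return self.classes_[np.argmax(score, axis=1)]

    # -- plain-JSON persistence ------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "coef_")
        payload = {
            "model": "intensity-svm-linear-ovo",
            "C": self.C,
            "classes": np.asarray(self.classes_).tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
            "scaler_mean": self.scaler_mean_.tolist(),
            "scaler_scale": self.scaler_scale_.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "IntensityClassifier":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        if payload.get("model") != "intensity-svm-linear-ovo":
            raise ValueError("not an intensity-classifier model file")
        clf = cls(C=payload["C"])
        clf.classes_ = np.asarray(payload["classes"])
        clf.coef_ = np.asarray(payload["coef"], dtype=float)
        clf.intercept_ = np.asarray(payload["intercept"], dtype=float)
        clf.scaler_mean_ = np.asarray(payload["scaler_mean"], dtype=float)
        clf.scaler_scale_ = np.asarray(payload["scaler_scale"], dtype=float)
        clf.n_features_in_ = clf.coef_.shape[1]
        return clf


def train_intensity_classifier(
    windows: Sequence[AccelWindow],
    train_frac: float = 0.7,
    seed: int | None = 0,
    C: float = 1.0,
) -> tuple[IntensityClassifier, ClassifierReport]:
    """Train the intensity SVM on labeled windows with a stratified split.

    Windows are featurized, split 70/30 stratified by level (a simple split
    over ~50 windows and 5 classes too easily drops a class), the classifier
    is fitted on the training part and evaluated on the held-out part.

    Raises
    ------
    ValueError
        If any of the five levels is absent or has fewer than two windows.
    """
    labels = [w.label for w in windows]
    if any(lab is None for lab in labels):
        raise ValueError("all windows must carry an intensity label")
    counts = {lev: labels.count(lev) for lev in INTENSITY_LEVELS}
    missing = [lev for lev, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"missing intensity level(s): {missing}")
    thin = [lev for lev, c in counts.items() if c < 2]
    if thin:
        raise ValueError(
            f"level(s) {thin} have fewer than 2 windows; stratified "
            "70/30 split needs at least one window on each side"
        )
    X = np.vstack([extract_features(w).as_array() for w in windows])
    y = np.asarray(labels, dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed
    )
    clf = IntensityClassifier(C=C).fit(X_tr, y_tr)
    y_hat = clf.predict(X_te)
    report = ClassifierReport(
        accuracy=float(np.mean(y_hat == y_te)),
        confusion=confusion_matrix(y_te, y_hat, labels=list(INTENSITY_LEVELS)),
        split_seed=seed,
        n_train=len(y_tr),
        n_test=len(y_te),
    )
    return clf, report


def classify(model: IntensityClassifier, features: FeatureVector) -> int:
    """Predict the intensity level (1-5) for a single feature vector."""
    if not isinstance(features, FeatureVector):
        features = FeatureVector(**asdict(features))
    return int(model.predict(features.as_array()[None, :])[0])
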