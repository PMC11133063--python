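"""Decision-making unit: a seeded random-forest over the six-feature vectors.

Classification is sample-wise — rows are treated independently, with all
temporal context already encoded in the features — so a plain ensemble of
decision trees suffices.  The hyperparameters are pinned in
:data:`DEFAULT_HYPERPARAMETERS` (and stored in every model artifact) so
"default settings" stays reproducible across library versions.  Class
scores are the fraction of trees voting for each class.  Alternative
classifiers can be plugged in through the same fit/predict_proba surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import TrainingError, ValidationError
from .features import FEATURE_NAMES, FeatureMatrix, concat_matrices

#: pinned forest settings; identical to scikit-learn 1.x defaults at pin time
DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 100,
    "criterion": "gini",
    "max_depth": None,
    "min_samples_split": 2,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
    "bootstrap": True,
}


@dataclass
class TrainedModel:
    """Fitted ensemble plus the metadata needed to reproduce it."""

    estimator: RandomForestClassifier
    class_set: tuple[int, ...]
    feature_order: tuple[str, ...]
    seed: int
    hyperparameters: dict = field(default_factory=dict)


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, FeatureMatrix):
        return data.features, data.label
    return concat_matrices(list(data))


def train_classifier(train, seed: int,
                     hyperparameters: dict | None = None) -> TrainedModel:
    """Fit the forest on one or more feature matrices.

    Raises :class:`TrainingError` for single-class input and
    :class:`ValidationError` (naming the first offending row) for
    non-finite features.
    """
    X, y = _as_xy(train)
    if X.shape[0] == 0:
        raise TrainingError("empty training set")
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        raise ValidationError(f"non-finite feature at row {int(np.flatnonzero(~finite)[0])}")
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise TrainingError(f"need >= 2 classes to train, got {classes}")
    hp = dict(DEFAULT_HYPERPARAMETERS)
    if hyperparameters:
        hp.update(hyperparameters)
    est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    est.fit(X, y)
    return TrainedModel(est, classes, FEATURE_NAMES, seed, hp)


def predict_labels(model: TrainedModel, test) -> tuple[np.ndarray, np.ndarray]:
    """Predict a class per row plus per-class scores (rows sum to 1).

    Score columns follow ``model.class_set`` order.
    """
    if isinstance(test, FeatureMatrix):
        X = test.features
    else:
        X = np.asarray(test, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_order):
        raise ValidationError(
            f"test matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"expected {len(model.feature_order)} ({model.feature_order})")
    if X.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty((0, len(model.class_set)))
    proba = model.estimator.predict_proba(X)
    pred = np.asarray(model.class_set)[np.argmax(proba, axis=1)]
    return pred, proba


def feature_importances(model: TrainedModel) -> np.ndarray:
    """Impurity-based importances, one non-negative weight per feature, summing to 1."""
    if not hasattr(model.estimator, "estimators_"):
        raise TrainingError("model is not trained")
    imp = model.estimator.feature_importances_
    s = imp.sum()
    return imp / s if s > 0 else np.full(len(imp), 1.0 / len(imp))


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({
        "estimator": model.estimator,
        "class_set": model.class_set,
        "feature_order": model.feature_order,
        "seed": model.seed,
        "hyperparameters": model.hyperparameters,
        "format_version": 1,
    }, path)


def load_model(path) -> TrainedModel:
    data = joblib.load(path)
    return TrainedModel(data["estimator"], tuple(data["class_set"]),
                        tuple(data["feature_order"]), int(data["seed"]),
                        dict(data["hyperparameters"]))
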