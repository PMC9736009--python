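"""Cross-validated classification of coefficient fingerprints.

Three model families mirror the study's comparison:

* ``lda`` -- linear discriminant analysis with a pooled full covariance,
  class priors from training frequencies and a tiny shrinkage
  regulariser so the pooled covariance is always invertible;
* ``svm_quadratic`` -- soft-margin SVM with a degree-2 polynomial kernel,
  kernel scale set automatically from the median pairwise distance of the
  (standardized) training features, one-vs-one multiclass voting;
* ``nn`` -- one fully connected hidden layer of 100 ReLU units with a
  softmax output, trained full-batch by L-BFGS with an L2 penalty and a
  fixed iteration cap.

Amplitude, frequency and phase coefficients live on wildly different
scales, so every family z-scores features using statistics of its
training fold only; the SVM kernel scale is likewise computed inside the
fold.  Nothing fitted ever sees a test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigurationError, StratificationError
from .features import FeatureMatrix

FAMILIES = ("lda", "svm_quadratic", "nn")

_DEFAULT_HYPERPARAMS = {
    "lda": {"shrinkage": 1e-6},
    "svm_quadratic": {"C": 1.0, "coef0": 1.0},
    "nn": {"hidden": 100, "alpha": 1e-4, "max_iter": 1000},
}


@dataclass(frozen=True)
class ModelSpec:
    """Validated classifier family + hyperparameters + seed."""

    family: str
    hyperparams: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown family '{self.family}'; expected one of {FAMILIES}"
            )
        allowed = set(_DEFAULT_HYPERPARAMS[self.family])
        unknown = set(self.hyperparams) - allowed
        if unknown:
            raise ConfigurationError(
                f"unknown hyperparameters for {self.family}: {sorted(unknown)}"
            )
        merged = {**_DEFAULT_HYPERPARAMS[self.family], **self.hyperparams}
        object.__setattr__(self, "hyperparams", merged)

    def to_dict(self) -> dict:
        return {"family": self.family, "hyperparams": dict(self.hyperparams), "seed": self.seed}


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified partition of sample indices into k folds."""

    folds: np.ndarray
    k: int

    def __post_init__(self):
        f = np.asarray(self.folds, int)
        if not set(np.unique(f)) <= set(range(self.k)):
            raise ConfigurationError("fold indices must lie in [0, k)")
        object.__setattr__(self, "folds", f)

    @property
    def n_samples(self) -> int:
        return self.folds.size

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


@dataclass(frozen=True)
class PredictionSet:
    """Out-of-fold predictions: one row per sample.

    Every prediction for fold f comes from a model that never saw fold f.
    """

    frame: pd.DataFrame  # sample_id, fold, true_label, predicted_label
    spec: ModelSpec

    def __post_init__(self):
        required = {"sample_id", "fold", "true_label", "predicted_label"}
        if not required <= set(self.frame.columns):
            raise ConfigurationError(f"prediction frame must have columns {sorted(required)}")

    @property
    def y_true(self) -> np.ndarray:
        return self.frame["true_label"].to_numpy(object)

    @property
    def y_pred(self) -> np.ndarray:
        return self.frame["predicted_label"].to_numpy(object)

    def accuracy(self) -> float:
        """Fraction of correct out-of-fold predictions, in percent."""
        return 100.0 * float(np.mean(self.y_true == self.y_pred))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def stratified_folds(labels, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Assign each sample to one of k folds, stratified by class.

    Per-class counts across folds differ by at most one; the assignment
    is a disjoint, exhaustive partition and is deterministic given seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise StratificationError(
            f"classes {list(too_small)} have fewer than k={k} samples"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(labels.size, int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((labels.size, 1)), labels)):
        folds[test_idx] = fold
    return FoldAssignment(folds=folds, k=k)


def _build_estimator(spec: ModelSpec, x_scaled: np.ndarray):
    hp = spec.hyperparams
    if spec.family == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=hp["shrinkage"])
    if spec.family == "svm_quadratic":
        med = float(np.median(pdist(x_scaled))) if x_scaled.shape[0] > 1 else 1.0
        if med <= 0:
            med = 1.0
        return SVC(
            kernel="poly",
            degree=2,
            gamma=1.0 / med**2,
            coef0=hp["coef0"],
            C=hp["C"],
        )
    return MLPClassifier(
        hidden_layer_sizes=(hp["hidden"],),
        activation="relu",
        solver="lbfgs",
        alpha=hp["alpha"],
        max_iter=hp["max_iter"],
        random_state=spec.seed,
    )


def train_predict(
    spec: ModelSpec,
    features_train: np.ndarray,
    labels_train,
    features_test: np.ndarray,
) -> np.ndarray:
    """Fit one classifier on a training split and predict a test split.

    Standardization (and the SVM kernel scale) is fitted on the training
    split only and applied to the test split.
    """
    x_train = np.asarray(features_train, float)
    x_test = np.asarray(features_test, float)
    y_train = np.asarray(labels_train)
    if not (np.all(np.isfinite(x_train)) and np.all(np.isfinite(x_test))):
        raise ConfigurationError("features must be finite")
    if np.unique(y_train).size < 2:
        raise ConfigurationError("training labels must contain at least two classes")
    scaler = StandardScaler().fit(x_train)
    xs_train = scaler.transform(x_train)
    xs_test = scaler.transform(x_test)
    estimator = _build_estimator(spec, xs_train)
    estimator.fit(xs_train, y_train)
    return np.asarray(estimator.predict(xs_test), dtype=object)


def cross_validate(
    spec: ModelSpec, features: FeatureMatrix, folds: FoldAssignment
) -> PredictionSet:
    """Out-of-fold predictions for every sample under a fold assignment."""
    if folds.n_samples != features.n_curves:
        raise ConfigurationError("fold assignment does not match the feature matrix")
    y = features.labels
    pred = np.empty(folds.n_samples, dtype=object)
    fold_of = np.asarray(folds.folds)
    for fold in range(folds.k):
        train_idx = folds.train_indices(fold)
        test_idx = folds.test_indices(fold)
        if test_idx.size == 0:
            continue
        try:
            pred[test_idx] = train_predict(
                spec, features.values[train_idx], y[train_idx], features.values[test_idx]
            )
        except Exception as exc:
            raise ConfigurationError(f"fold {fold}: {exc}") from exc
    frame = pd.DataFrame(
        {
            "sample_id": np.arange(folds.n_samples),
            "fold": fold_of,
            "true_label": y,
            "predicted_label": pred,
        }
    )
    return PredictionSet(frame=frame, spec=spec)
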