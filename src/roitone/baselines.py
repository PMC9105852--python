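"""Classical classifiers on flattened ROI pixel vectors.

k-NN (k = 1, 3, 5), linear SVM, LDA and a 100-tree random forest, all
consuming the identical row-major flattening of each patch (pixel (r, c)
maps to column r*size + c) scaled to [0, 1] by fmax division — the same
input contract as the CNN, so differences in error are attributable to the
classifier alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .synthdata import LabeledDataset

__all__ = [
    "BaselineMethod",
    "BaselineSpec",
    "flatten_features",
    "fit_predict_baseline",
    "BaselineClassifier",
    "baseline_factory",
    "STANDARD_BASELINES",
]


class BaselineMethod(str, enum.Enum):
    KNN = "knn"
    SVM_LINEAR = "svm_linear"
    LDA = "lda"
    RF = "rf"


@dataclass(frozen=True)
class BaselineSpec:
    """One classical classifier: method plus its single knob.

    ``k`` (odd, >= 1) applies to k-NN only; ``n_trees`` to the random forest
    only.  ``seed`` matters only for the stochastic random forest.
    """

    method: BaselineMethod
    k: int = 1
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", BaselineMethod(self.method))
        if self.method is BaselineMethod.KNN and (self.k < 1 or self.k % 2 == 0):
            raise ValueError(f"k must be odd and >= 1, got {self.k}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def label(self) -> str:
        if self.method is BaselineMethod.KNN:
            return f"{self.k}-NN"
        return {"svm_linear": "SVM", "lda": "LDA", "rf": "RF"}[self.method.value]


#: the comparison battery: 1/3/5-NN, linear SVM, LDA, 100-tree RF
STANDARD_BASELINES = (
    BaselineSpec(BaselineMethod.KNN, k=1),
    BaselineSpec(BaselineMethod.KNN, k=3),
    BaselineSpec(BaselineMethod.KNN, k=5),
    BaselineSpec(BaselineMethod.SVM_LINEAR),
    BaselineSpec(BaselineMethod.LDA),
    BaselineSpec(BaselineMethod.RF),
)


def flatten_features(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    """Row-major flattening: (n, size, size) images -> (n, size*size) floats.

    Returned features are raw grey levels (no scaling); labels are the
    dataset's 0/1 class codes.
    """
    n = len(dataset)
    x = dataset.images.reshape(n, -1).astype(np.float64)
    return x, dataset.labels.astype(np.int64)


def _make_estimator(spec: BaselineSpec):
    if spec.method is BaselineMethod.KNN:
        return KNeighborsClassifier(n_neighbors=spec.k, metric="euclidean")
    if spec.method is BaselineMethod.SVM_LINEAR:
        return SVC(kernel="linear", C=1.0)
    if spec.method is BaselineMethod.LDA:
        # svd solver: pooled-covariance discriminant, stable when the
        # covariance is singular (1024 features vs a few hundred samples)
        return LinearDiscriminantAnalysis(solver="svd")
    if spec.method is BaselineMethod.RF:
        return RandomForestClassifier(n_estimators=spec.n_trees, random_state=spec.seed)
    raise AssertionError(spec.method)


def fit_predict_baseline(
    spec: BaselineSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
) -> np.ndarray:
    """Fit the specified classifier and return test predictions."""
    x_train = np.asarray(x_train, dtype=np.float64)
    x_test = np.asarray(x_test, dtype=np.float64)
    if x_train.shape[1] != x_test.shape[1]:
        raise ValueError(
            f"train/test feature widths differ: {x_train.shape[1]} vs {x_test.shape[1]}"
        )
    if spec.method is BaselineMethod.LDA and len(np.unique(y_train)) < 2:
        raise ValueError("LDA requires at least two classes in the training set")
    est = _make_estimator(spec)
    est.fit(x_train, y_train)
    return np.asarray(est.predict(x_test))


class BaselineClassifier:
    """Holdout-protocol adapter around :func:`fit_predict_baseline`."""

    def __init__(self, spec: BaselineSpec):
        self.spec = spec
        self._est = None
        self._fmax = 255

    def fit(self, images: np.ndarray, labels: np.ndarray, fmax: int = 255):
        self._fmax = fmax
        x = np.asarray(images, np.float64).reshape(len(images), -1) / fmax
        if self.spec.method is BaselineMethod.LDA and len(np.unique(labels)) < 2:
            raise ValueError("LDA requires at least two classes in the training set")
        self._est = _make_estimator(self.spec)
        self._est.fit(x, np.asarray(labels, np.int64))
        return self

    def predict(self, images: np.ndarray) -> np.ndarray:
        if self._est is None:
            raise RuntimeError("classifier not fitted")
        x = np.asarray(images, np.float64).reshape(len(images), -1) / self._fmax
        return np.asarray(self._est.predict(x))


def baseline_factory(spec: BaselineSpec):
    """Per-trial factory for the holdout protocol; the seed reaches the RF."""

    def make(seed: int) -> BaselineClassifier:
        return BaselineClassifier(replace(spec, seed=int(seed) % 2**31))

    return make
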