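"""Nodule vs suspected-nodule classification.

Two classifiers are provided:

* a baseline one-hidden-layer feed-forward network (backpropagation-trained
  MLP) on the 51 handcrafted features;
* a fusion classifier that concatenates a deep embedding of the ROI volume
  with the handcrafted features *in series* (embedding first, then the 51
  handcrafted values) before the same dense head.

The embedding producer is a contract, not a fixed architecture: any object
with a deterministic ``embed(volume) -> 1D array`` and an ``embedding_dim``
satisfies it.  The built-in :class:`RandomConvBackbone` computes seeded
random-filter 3D convolutional features (untrained random projections
followed by ReLU and global statistics pooling) — deterministic, dependency-
free, and sufficient to exercise the fusion pathway; a pretrained image
backbone can be dropped in through the same contract.

Feature standardization (z-score) is always fit on the training split only.
Splits are stratified by label and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import DataError
from .features import handcrafted
from .metrics import MetricReport, classification_metrics, confusion

POSITIVE_LABEL = "nodule"
DEFAULT_SPLIT_RATIO = 0.8


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, stratified train/test index partition of a dataset."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    split_ratio: float

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise DataError("train and test indices overlap")


def split_dataset(labels: Sequence, ratio: float = DEFAULT_SPLIT_RATIO,
                  seed: int = 0) -> DatasetSplit:
    """Stratified seeded split into train/test with the given train ratio.

    Each class contributes ``round((1 - ratio) * n_class)`` samples (at
    least one) to the test set.  Classes with fewer than two samples are
    rejected.
    """
    labels = np.asarray(labels)
    if not 0 < ratio < 1:
        raise DataError(f"split ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 2:
            raise DataError(f"class {cls!r} has fewer than 2 samples")
        idx = rng.permutation(idx)
        n_test = max(1, round((1 - ratio) * idx.size))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return DatasetSplit(
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)),
        split_ratio=ratio,
    )


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and optimization settings of the dense classifier head."""

    hidden_units: int = 32
    activation: str = "logistic"
    max_iter: int = 1500
    learning_rate_init: float = 0.01
    alpha: float = 1e-4
    seed: int = 0


@dataclass
class FittedClassifier:
    """A standardizer + MLP pair fit on a training split."""

    scaler: StandardScaler
    model: MLPClassifier
    feature_names: list[str] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.scaler.transform(np.asarray(X, dtype=float)))

    @property
    def loss_curve(self) -> list[float]:
        return list(self.model.loss_curve_)


def _check_finite(X: np.ndarray, names: list[str] | None) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        col = int(np.nonzero(bad.any(axis=0))[0][0])
        label = names[col] if names and col < len(names) else f"column {col}"
        raise DataError(f"non-finite feature values in {label}")


def train_mlp(X: np.ndarray, y: Sequence, config: MLPConfig = MLPConfig(),
              feature_names: list[str] | None = None) -> FittedClassifier:
    """Train the feed-forward classifier on (already split) training data.

    Features are z-scored with statistics of this training set; the network
    has one hidden layer and is trained by backpropagation with a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DataError("training data must contain at least two classes")
    _check_finite(X, feature_names)
    scaler = StandardScaler().fit(X)
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation=config.activation,
        max_iter=config.max_iter,
        learning_rate_init=config.learning_rate_init,
        alpha=config.alpha,
        random_state=config.seed,
    )
    model.fit(scaler.transform(X), y)
    return FittedClassifier(scaler=scaler, model=model, feature_names=feature_names)


@runtime_checkable
class BackboneContract(Protocol):
    """Anything that deterministically embeds a volume into a fixed-length vector."""

    embedding_dim: int

    def embed(self, volume: np.ndarray) -> np.ndarray: ...


@dataclass
class RandomConvBackbone:
    """Seeded random-filter 3D convolutional embedding (untrained).

    ``n_filters`` random 3x3x3 kernels are correlated with the volume; each
    response map passes through ReLU and is pooled into four global
    statistics (mean, std, max, 90th percentile), giving
    ``embedding_dim = 4 * n_filters``.  Same volume, same seed => same
    embedding.
    """

    n_filters: int = 16
    seed: int = 0
    _kernels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        self._kernels = rng.standard_normal((self.n_filters, 3, 3, 3))
        self.embedding_dim = 4 * self.n_filters

    def embed(self, volume: np.ndarray) -> np.ndarray:
        volume = np.asarray(volume, dtype=float)
        out = np.empty(self.embedding_dim)
        for i, kernel in enumerate(self._kernels):
            resp = np.maximum(ndimage.correlate(volume, kernel, mode="reflect"), 0.0)
            out[4 * i: 4 * i + 4] = (resp.mean(), resp.std(), resp.max(),
                                     np.percentile(resp, 90))
        return out


@dataclass
class ConstantBackbone:
    """An uninformative embedding (all zeros); the fusion sanity reduction."""

    embedding_dim: int = 8

    def embed(self, volume: np.ndarray) -> np.ndarray:
        return np.zeros(self.embedding_dim)


def fuse(embedding: np.ndarray, handcrafted_vec: np.ndarray) -> np.ndarray:
    """Serial feature fusion: deep embedding first, then the handcrafted values."""
    embedding = np.asarray(embedding, dtype=float).ravel()
    handcrafted_vec = np.asarray(handcrafted_vec, dtype=float).ravel()
    if embedding.size == 0 or handcrafted_vec.size == 0:
        raise DataError("fusion requires nonempty embedding and handcrafted vectors")
    return np.concatenate([embedding, handcrafted_vec])


@dataclass(frozen=True)
class ExperimentResult:
    """Outcome of a train/evaluate run on one split."""

    classifier: FittedClassifier
    split: DatasetSplit
    predictions: np.ndarray      # test-split predictions
    test_labels: np.ndarray
    report: MetricReport

    @property
    def accuracy(self) -> float:
        return self.report.accuracy


def _positive_label(y: np.ndarray):
    classes = np.unique(y)
    return POSITIVE_LABEL if POSITIVE_LABEL in classes else classes[0]


def _evaluate(clf: FittedClassifier, X_test: np.ndarray, y_test: np.ndarray,
              split: DatasetSplit) -> ExperimentResult:
    pred = clf.predict(X_test)
    positive = _positive_label(np.asarray(y_test))
    c = confusion(pred == positive, np.asarray(y_test) == positive)
    return ExperimentResult(classifier=clf, split=split, predictions=pred,
                            test_labels=np.asarray(y_test),
                            report=classification_metrics(c))


def train_and_evaluate(X: np.ndarray, y: Sequence, config: MLPConfig = MLPConfig(),
                       ratio: float = DEFAULT_SPLIT_RATIO, seed: int = 0,
                       feature_names: list[str] | None = None) -> ExperimentResult:
    """Split a feature table, train the MLP on train, evaluate on test."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    split = split_dataset(y, ratio=ratio, seed=seed)
    clf = train_mlp(X[split.train_idx], y[split.train_idx], config, feature_names)
    return _evaluate(clf, X[split.test_idx], y[split.test_idx], split)


def train_fusion(volumes: Sequence[np.ndarray], y: Sequence,
                 backbone: BackboneContract, config: MLPConfig = MLPConfig(),
                 ratio: float = DEFAULT_SPLIT_RATIO, seed: int = 0) -> ExperimentResult:
    """Fusion pipeline: embed + handcrafted + serial fusion + dense head.

    The backbone is frozen (used for inference only); the dense head is
    trained on the training split of the fused features.
    """
    y = np.asarray(y)
    try:
        fused = np.stack([fuse(backbone.embed(v), handcrafted(v)) for v in volumes])
    except Exception as exc:
        raise DataError(f"backbone embedding failed: {exc}") from exc
    split = split_dataset(y, ratio=ratio, seed=seed)
    clf = train_mlp(fused[split.train_idx], y[split.train_idx], config)
    return _evaluate(clf, fused[split.test_idx], y[split.test_idx], split)
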