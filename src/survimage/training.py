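"""Classifier training, evaluation, hyperparameter grids and the age sweep.

The classification task is binary: does a difference image depict the
longer-survival pattern (``TLS``, the positive class) or its negation
(``TSL``)? Accuracy is the usual confusion-matrix ratio
``(TP + TN) / (P + N)``; because every pair contributes exactly one image of
each class, the task is balanced and 0.5 is the chance floor.

Three desk-scale architectures are registered:

``tiny``
    The numpy convolutional net from :mod:`survimage.nets`, trained with
    Adam, cross-entropy and dropout 0.4 (the fixed settings of the full-scale
    protocol).
``logreg``
    L2 logistic regression on flattened pixels — a fast linear reference used
    by the age-cutoff sweep.
``mlp``
    A one-hidden-layer perceptron (scikit-learn), also Adam + cross-entropy.

The default hyperparameter grid couples epochs and batch size in the three
pairs (50, 8), (100, 16), (150, 32).

The age sweep re-splits the cohort at every candidate cutoff, builds TLS/TSL
images *within* each stratum's train and test subsets (pairs never cross the
train/test boundary or the stratum boundary), merges the two training image
sets and the two test image sets, trains one model, and records test
accuracy per cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .cohort import Cohort, CohortError, stratified_split
from .imaging import DifferenceImage, build_image_set
from .nets import TinyConvNet

__all__ = [
    "TrainConfig",
    "EvalResult",
    "TrainedModel",
    "TrainingError",
    "HYPERPARAMETER_GRID",
    "ARCHITECTURES",
    "images_to_arrays",
    "train_model",
    "evaluate",
    "accuracy_from_counts",
    "grid_search",
    "age_sweep",
    "AgeSweepResult",
]

#: (epochs, batch_size) combinations of the full-scale protocol.
HYPERPARAMETER_GRID = ((50, 8), (100, 16), (150, 32))

#: Registered architectures, ordered smallest first (grid-search tie-break).
ARCHITECTURES = ("logreg", "tiny", "mlp")

#: Default cutoff range of the age sweep (cohort age quartiles Q1..Q3).
DEFAULT_CUTOFFS = range(48, 70)


class TrainingError(ValueError):
    """Raised for invalid training inputs or unknown architectures."""


@dataclass(frozen=True)
class TrainConfig:
    """Architecture plus hyperparameters; optimizer, loss and dropout fixed.

    ``epochs``/``batch_size`` default to the first grid pair. For the
    scikit-learn architectures ``epochs`` caps the number of optimizer
    iterations and ``batch_size``/``dropout`` are ignored where inapplicable.
    """

    architecture: str = "tiny"
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    dropout: float = 0.4
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "cross_entropy"


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts with TLS as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> float:
        return accuracy_from_counts(self.tp, self.tn, self.fp, self.fn)


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (P + N)."""
    total = tp + tn + fp + fn
    if total == 0:
        raise TrainingError("no predictions to score")
    return (tp + tn) / total


def images_to_arrays(
    images: list[DifferenceImage],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into ``(X, y)``: pixels scaled to [0, 1], TLS mapped to 1."""
    if not images:
        raise TrainingError("empty image set")
    side = images[0].side
    if any(img.side != side for img in images):
        raise TrainingError("images have mismatched dimensions")
    X = np.stack([img.pixels for img in images]).astype(np.float64) / 255.0
    y = np.array([1 if img.label == "TLS" else 0 for img in images], dtype=np.int64)
    return X, y


class TrainedModel:
    """A fitted classifier plus the image geometry it was trained on."""

    def __init__(self, backend, side: int, cfg: TrainConfig):
        self.backend = backend
        self.side = side
        self.cfg = cfg

    @property
    def history(self) -> list[float]:
        """Per-epoch mean training loss (``tiny``) or per-iteration loss curve."""
        if isinstance(self.backend, TinyConvNet):
            return self.backend.history
        return list(getattr(self.backend, "loss_curve_", []))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class indices (1 = TLS) for a stack of ``(N, side, side)`` images."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != (self.side, self.side):
            raise TrainingError(
                f"expected images of side {self.side}, got shape {X.shape}"
            )
        if isinstance(self.backend, TinyConvNet):
            return self.backend.predict(X)
        return self.backend.predict(X.reshape(X.shape[0], -1))

    def predict_images(self, images: list[DifferenceImage]) -> list[str]:
        """Label strings for a list of difference images."""
        X = np.stack([img.pixels for img in images]).astype(np.float64) / 255.0
        return ["TLS" if c == 1 else "TSL" for c in self.predict(X)]


def train_model(
    train_images: list[DifferenceImage], cfg: TrainConfig
) -> TrainedModel:
    """Fit the configured classifier on labeled TLS/TSL images.

    Raises
    ------
    TrainingError
        On an empty or single-class training set, mismatched image
        dimensions, or an unknown architecture.
    """
    X, y = images_to_arrays(train_images)
    if len(set(y.tolist())) < 2:
        raise TrainingError("training set contains a single class")
    side = train_images[0].side

    if cfg.architecture == "tiny":
        net = TinyConvNet(side=side, dropout=cfg.dropout, seed=cfg.seed)
        net.fit(
            X,
            y,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
        )
        return TrainedModel(net, side, cfg)

    flat = X.reshape(X.shape[0], -1)
    if cfg.architecture == "logreg":
        clf = LogisticRegression(max_iter=max(cfg.epochs, 1000))
        clf.fit(flat, y)
        return TrainedModel(clf, side, cfg)
    if cfg.architecture == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(32,),
            solver="adam",
            learning_rate_init=cfg.learning_rate,
            batch_size=min(cfg.batch_size, X.shape[0]),
            max_iter=cfg.epochs,
            random_state=cfg.seed,
        )
        clf.fit(flat, y)
        return TrainedModel(clf, side, cfg)
    raise TrainingError(
        f"unknown architecture {cfg.architecture!r}; available: {ARCHITECTURES}"
    )


def evaluate(model: TrainedModel, test_images: list[DifferenceImage]) -> EvalResult:
    """Confusion counts and accuracy on a labeled test image set."""
    if not test_images:
        raise TrainingError("empty test set")
    X, y = images_to_arrays(test_images)
    pred = model.predict(X)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return EvalResult(tp=tp, tn=tn, fp=fp, fn=fn)


def grid_search(
    train_images: list[DifferenceImage],
    test_images: list[DifferenceImage],
    architectures: list[str],
    combos: list[tuple[int, int]] = HYPERPARAMETER_GRID,
    base: TrainConfig = TrainConfig(),
) -> tuple[pd.DataFrame, TrainConfig]:
    """Train/evaluate every (architecture, epochs, batch) cell.

    Returns the accuracy table (one row per cell) and the best configuration.
    Ties are broken by fewer epochs, then by smaller architecture (the
    registry order of :data:`ARCHITECTURES`).
    """
    if not architectures or not combos:
        raise TrainingError("empty architecture or hyperparameter grid")
    rows = []
    for arch in architectures:
        for epochs, batch in combos:
            cfg = replace(base, architecture=arch, epochs=epochs, batch_size=batch)
            model = train_model(train_images, cfg)
            acc = evaluate(model, test_images).accuracy
            rows.append(
                {
                    "architecture": arch,
                    "epochs": epochs,
                    "batch_size": batch,
                    "accuracy": acc,
                }
            )
    table = pd.DataFrame(rows)

    def size_rank(a: str) -> int:
        return ARCHITECTURES.index(a) if a in ARCHITECTURES else len(ARCHITECTURES)

    best = min(rows, key=lambda r: (-r["accuracy"], r["epochs"], size_rank(r["architecture"])))
    best_cfg = replace(
        base,
        architecture=best["architecture"],
        epochs=best["epochs"],
        batch_size=best["batch_size"],
    )
    return table, best_cfg


@dataclass
class AgeSweepResult:
    """Accuracy per evaluated cutoff; unevaluable cutoffs are omitted."""

    accuracies: dict[int, float]
    best_cutoff: int

    @property
    def curve(self) -> pd.Series:
        return pd.Series(self.accuracies).sort_index()


def age_sweep(
    c: Cohort,
    cutoffs=DEFAULT_CUTOFFS,
    cfg: TrainConfig = TrainConfig(),
    train_frac: float = 0.7,
    split_seed: int = 0,
    rounding: str = "ceil",
) -> AgeSweepResult:
    """Test accuracy of the full pipeline at every age cutoff.

    Per cutoff: stratified 70/30 split, per-stratum pair imaging of the train
    and test subsets separately, merge across strata, train, evaluate. A
    cutoff whose split is degenerate (a stratum with fewer than two members,
    or a single-class training set) is skipped rather than fatal.
    """
    accuracies: dict[int, float] = {}
    for cutoff in cutoffs:
        try:
            spec = stratified_split(
                c, cutoff, train_frac=train_frac, seed=split_seed, rounding=rounding
            )
            train_images: list[DifferenceImage] = []
            test_images: list[DifferenceImage] = []
            for stratum in ("YOUNG", "OLD"):
                train_images.extend(build_image_set(c, spec.train_of(stratum)))
                test_images.extend(build_image_set(c, spec.test_of(stratum)))
            model = train_model(train_images, cfg)
            accuracies[int(cutoff)] = evaluate(model, test_images).accuracy
        except (CohortError, TrainingError):
            continue
    if not accuracies:
        raise TrainingError("no cutoff could be evaluated")
    best = min(accuracies, key=lambda k: (-accuracies[k], k))
    return AgeSweepResult(accuracies=accuracies, best_cutoff=best)
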