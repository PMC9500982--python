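"""Label binarization, splits, loss, SGD training loop and metrics.

Ratings on the 1-9 scale are thresholded at five into low/high classes
(the boundary itself counts as low).  Training minimises mean cross-entropy
with plain SGD, mini-batches of 32, an initial learning rate of 0.01 decayed
by 0.9 every 10 epochs, and a fixed 90-epoch budget; evaluation reports
recall, precision, F1 and accuracy from the confusion counts, with "high"
as the positive class, averaged over repeated random 80/20 splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .architectures import ModelSpec
from .backend import NumpyModel, SGD, softmax, softmax_cross_entropy
from .montage import WindowDataset

logger = logging.getLogger(__name__)


def binarize_rating(rating: float, threshold: float = 5.0) -> int:
    """1-9 rating -> binary label; high iff rating > threshold."""
    if not 1.0 <= rating <= 9.0:
        raise ValueError(f"rating must lie in [1, 9], got {rating}")
    return int(rating > threshold)


def split_dataset(dataset: WindowDataset, fraction: float = 0.8,
                  seed: int = 0) -> tuple[WindowDataset, WindowDataset]:
    """Uniformly random window-level partition into train/test."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must lie in (0, 1), got {fraction}")
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fraction * n + 0.5))
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


def cross_entropy_loss(y: Sequence[int], y_hat: Sequence[float], eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, natural log, probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"label/probability shapes differ: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("cannot compute the loss of zero samples")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class TrainConfig:
    """Optimization schedule and evaluation protocol."""

    batch_size: int = 32
    initial_lr: float = 0.01
    lr_decay: float = 0.9
    lr_decay_every: int = 10
    epochs: int = 90
    momentum: float = 0.0
    weight_decay: float = 0.0
    seed: int = 0
    split_fraction: float = 0.8
    repeats: int = 5
    target_accuracy: float | None = None  # optional early exit for smoke runs

    def __post_init__(self):
        for name in ("batch_size", "initial_lr", "lr_decay", "lr_decay_every", "epochs", "repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError(f"split_fraction must lie in (0, 1), got {self.split_fraction}")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index (x0.9 every 10 epochs)."""
        return self.initial_lr * self.lr_decay ** (epoch // self.lr_decay_every)


@dataclass
class TrainedModel:
    model: NumpyModel
    task: str
    history: pd.DataFrame

    def predict_proba(self, tensors: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Probability of the high class per window."""
        x = _as_model_input(tensors)
        probs = []
        for start in range(0, len(x), batch_size):
            logits = self.model.forward(x[start:start + batch_size], train=False)
            probs.append(softmax(logits)[:, 1])
        return np.concatenate(probs)

    def predict(self, tensors: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return (self.predict_proba(tensors, batch_size) > 0.5).astype(int)


def _as_model_input(tensors: np.ndarray) -> np.ndarray:
    """(N, D, H, W) windows -> (N, 1, D, H, W) single-channel model input."""
    x = np.asarray(tensors, dtype=np.float64)
    if x.ndim == 4:
        x = x[:, None]
    return x


def train_model(spec: ModelSpec, dataset: WindowDataset, task: str,
                config: TrainConfig | None = None,
                dtype=np.float32) -> TrainedModel:
    """Minimize cross-entropy over mini-batches; fully seed-reproducible.

    History records loss and training accuracy per epoch (aggregated over
    the mini-batch forward passes of that epoch).  Training runs in single
    precision by default; pass ``dtype=np.float64`` for double.
    """
    config = config or TrainConfig()
    labels = dataset.labels(task)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("dataset labels must be binary")
    x = _as_model_input(dataset.tensors).astype(dtype)
    model = NumpyModel.from_spec(spec, seed=config.seed, dtype=dtype)
    opt = SGD(model.parameters(), lr=config.initial_lr,
              momentum=config.momentum, weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    history = []
    n = len(x)
    for epoch in range(config.epochs):
        opt.lr = config.learning_rate(epoch)
        perm = shuffle_rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, yb = x[idx], labels[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"lr={opt.lr:g}; reduce the learning rate"
                )
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        epoch_loss = float(np.sum(losses) / n)
        epoch_acc = correct / n
        history.append({"epoch": epoch, "lr": opt.lr, "loss": epoch_loss,
                        "train_accuracy": epoch_acc})
        if config.target_accuracy is not None and epoch_acc >= config.target_accuracy:
            logger.info("target train accuracy %.3f reached at epoch %d",
                        config.target_accuracy, epoch)
            break
    return TrainedModel(model=model, task=task, history=pd.DataFrame(history))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_matrix(self) -> pd.DataFrame:
        """2x2 matrix, rows = actual (low/high), columns = predicted."""
        return pd.DataFrame(
            [[self.tn, self.fp], [self.fn, self.tp]],
            index=["actual_low", "actual_high"],
            columns=["pred_low", "pred_high"],
        )


def confusion_counts(predicted: Sequence[int], actual: Sequence[int]) -> ConfusionCounts:
    """Binary confusion counts with the high class as positive."""
    pred = np.asarray(predicted, dtype=int)
    act = np.asarray(actual, dtype=int)
    if pred.shape != act.shape:
        raise ValueError(f"length mismatch: {pred.shape} predicted vs {act.shape} actual")
    if pred.size == 0:
        raise ValueError("cannot build confusion counts from zero samples")
    return ConfusionCounts(
        tp=int(((pred == 1) & (act == 1)).sum()),
        tn=int(((pred == 0) & (act == 0)).sum()),
        fp=int(((pred == 1) & (act == 0)).sum()),
        fn=int(((pred == 0) & (act == 1)).sum()),
    )


@dataclass(frozen=True)
class MetricsRecord:
    recall: float
    precision: float
    f1: float
    accuracy: float
    degenerate: tuple[str, ...] = ()


def compute_metrics(c: ConfusionCounts) -> MetricsRecord:
    """Recall, precision, F1 and accuracy; zero denominators yield 0, flagged."""
    if c.total == 0:
        raise ValueError("confusion counts are empty")
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            logger.warning("%s undefined (zero denominator); reporting 0", name)
            return 0.0
        return num / den

    recall = ratio(c.tp, c.tp + c.fn, "recall")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = (c.tp + c.tn) / c.total
    return MetricsRecord(recall=recall, precision=precision, f1=f1,
                         accuracy=accuracy, degenerate=tuple(degenerate))


@dataclass
class RepeatedEvaluation:
    """Per-repeat metrics and confusion matrices plus a mean (SD) summary."""

    task: str
    per_repeat: pd.DataFrame
    confusions: list[ConfusionCounts]

    @property
    def summary(self) -> pd.DataFrame:
        """Mean and population SD of each metric across repeats."""
        metrics = self.per_repeat[["recall", "precision", "f1", "accuracy"]]
        return pd.DataFrame({"mean": metrics.mean(), "sd": metrics.std(ddof=0)})


def run_repeated_evaluation(
    spec: ModelSpec,
    dataset: WindowDataset,
    task: str,
    config: TrainConfig | None = None,
) -> RepeatedEvaluation:
    """Repeat (fresh split -> train -> test) and aggregate the metrics.

    Repeat ``r`` uses split seed ``config.seed + r`` and the same training
    seed offsetting, so two invocations with identical configs produce
    identical tables.
    """
    config = config or TrainConfig()
    rows = []
    confusions = []
    for r in range(config.repeats):
        train_set, test_set = split_dataset(dataset, config.split_fraction,
                                            seed=config.seed + r)
        trained = train_model(spec, train_set, task,
                              replace(config, seed=config.seed + r))
        pred = trained.predict(test_set.tensors)
        counts = confusion_counts(pred, test_set.labels(task))
        m = compute_metrics(counts)
        confusions.append(counts)
        rows.append({"repeat": r, "recall": m.recall, "precision": m.precision,
                     "f1": m.f1, "accuracy": m.accuracy,
                     "final_train_loss": trained.history["loss"].iloc[-1]})
    return RepeatedEvaluation(task=task, per_repeat=pd.DataFrame(rows),
                              confusions=confusions)
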