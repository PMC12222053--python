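"""Fold-wise training of the SFCN and classification metrics.

Training minimizes softmax cross-entropy with a stochastic-gradient
optimizer using decoupled weight decay (AdamW-style adaptive update by
default, momentum SGDW available).  The checkpoint with the best
validation accuracy is kept, and per-epoch accuracy curves are recorded.
The positive class for precision/recall is label 1, which the task
definitions reserve for the illusion-occurrence class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .dataset import FoldSpec, LabeledSampleSet, undersample_majority
from .sfcn import SFCN, SFCNConfig, build_sfcn

#: per-task optimized hyperparameters (learning rate, weight decay, batch).
TASK_HYPERPARAMS = {
    "aristotle_vs_reverse": (1e-3, 0.4, 64),
    "reverse_vs_async": (1e-3, 0.4, 64),
    "aristotle_vs_async": (1e-3, 0.4, 64),
    "aristotle_illusion_vs_reverse_illusion": (3e-4, 0.4, 32),
    "reverse_illusion_vs_no_reverse_illusion": (1e-5, 0.2, 16),
}


@dataclass(frozen=True)
class TrainConfig:
    task: str = "aristotle_illusion_vs_reverse_illusion"
    lr: float = 3e-4
    weight_decay: float = 0.4
    batch_size: int = 32
    epochs: int = 50
    optimizer: str = "adamw"        # "adamw" | "sgdw"
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "TrainConfig":
        lr, wd, bs = TASK_HYPERPARAMS.get(task, (3e-4, 0.4, 32))
        kw = dict(task=task, lr=lr, weight_decay=wd, batch_size=bs)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class Metrics:
    """Binary classification metrics from confusion counts.

    Positive class = label 1.  F1 is defined as 0 when precision + recall
    is 0 (no positive predictions and no positives recalled).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "Metrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()))

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


@dataclass
class TrainResult:
    model: SFCN
    curves: pd.DataFrame          # epoch, train_loss, train_acc, val_acc
    best_epoch: int
    best_val_acc: float


def _as_batch_input(x: np.ndarray) -> np.ndarray:
    """(n, d, h, w) -> (n, 1, d, h, w) float32."""
    return np.ascontiguousarray(x[:, None], dtype=np.float32)


def _make_optimizer(model: SFCN, config: TrainConfig):
    if config.optimizer == "adamw":
        return nn.AdamW(model.params(), lr=config.lr,
                        weight_decay=config.weight_decay)
    if config.optimizer == "sgdw":
        return nn.SGDW(model.params(), lr=config.lr,
                       weight_decay=config.weight_decay,
                       momentum=config.momentum)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def evaluate(model: SFCN, val_set: LabeledSampleSet,
             batch_size: int = 32) -> Metrics:
    """Score argmax predictions on a validation set (eval mode)."""
    if len(val_set) == 0:
        raise ValueError("empty validation set")
    preds = model.predict(_as_batch_input(val_set.samples),
                          batch_size=batch_size)
    return Metrics.from_predictions(val_set.labels, preds)


def train_fold(model: SFCN, train_set: LabeledSampleSet,
               val_set: LabeledSampleSet, config: TrainConfig) -> TrainResult:
    """Train one fold; restore and return the best-validation checkpoint."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = _make_optimizer(model, config)
    x_train = _as_batch_input(train_set.samples)
    y_train = train_set.labels.astype(int)
    rows = []
    best = (-1.0, None, -1)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(y_train))
        losses, correct = [], 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            model.zero_grads()
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={config.lr}, wd={config.weight_decay}); aborting")
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        train_acc = correct / len(y_train)
        val_acc = evaluate(model, val_set, config.batch_size).accuracy
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "train_acc": train_acc, "val_acc": val_acc})
        # ties broken toward the later epoch: among equally accurate
        # checkpoints the most-trained one has the better-formed features
        if val_acc >= best[0]:
            best = (val_acc, model.get_state(), epoch)
    if best[1] is not None:
        model.set_state(best[1])
    curves = pd.DataFrame(rows)
    return TrainResult(model=model, curves=curves, best_epoch=best[2],
                       best_val_acc=best[0])


@dataclass
class CVResult:
    fold_metrics: list            # list of Metrics
    mean_metrics: dict            # arithmetic means of the four scores
    models: list                  # best checkpoint per fold
    fold_val_indices: list        # validation sample indices per fold
    curves: list                  # per-fold curve DataFrames

    def metrics_frame(self) -> pd.DataFrame:
        rows = [dict(fold=i + 1, **m.as_dict())
                for i, m in enumerate(self.fold_metrics)]
        rows.append(dict(fold="mean", **{k: v for k, v
                                         in self.mean_metrics.items()}))
        return pd.DataFrame(rows)


def cross_validate(sample_set: LabeledSampleSet, folds: FoldSpec,
                   config: TrainConfig, model_config: SFCNConfig,
                   undersample: bool = True) -> CVResult:
    """Train one model per fold (undersampling the training majority class)
    and aggregate metric means.  Validation sets are never resampled."""
    fold_metrics, models, val_indices, curves = [], [], [], []
    for f, (train_idx, val_idx) in enumerate(folds.folds):
        train_set = sample_set.subset(train_idx)
        val_set = sample_set.subset(val_idx)
        if undersample:
            train_set = undersample_majority(
                train_set, seed=int(np.random.default_rng(
                    [config.seed, 101, f]).integers(2 ** 31)))
        model = build_sfcn(replace(model_config,
                                   seed=int(np.random.default_rng(
                                       [config.seed, 202, f]).integers(2 ** 31))))
        fold_cfg = replace(config, seed=int(np.random.default_rng(
            [config.seed, 303, f]).integers(2 ** 31)))
        result = train_fold(model, train_set, val_set, fold_cfg)
        fold_metrics.append(evaluate(result.model, val_set, config.batch_size))
        models.append(result.model)
        val_indices.append(val_idx)
        curves.append(result.curves)
    mean = {k: float(np.mean([m.as_dict()[k] for m in fold_metrics]))
            for k in ("accuracy", "precision", "recall", "f1")}
    return CVResult(fold_metrics=fold_metrics, mean_metrics=mean,
                    models=models, fold_val_indices=val_indices, curves=curves)
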