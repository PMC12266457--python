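"""Training protocol: Adam + categorical cross-entropy with checkpointing
on best validation burnt-class IoU, learning-rate reduction on plateau
(factor 0.9, patience 10, floor 1e-7) and early stopping.

The monitored quantity is the burnt-class IoU of argmax predictions on the
validation set — the quantity checkpointing and both callbacks watch.
"An improvement" is any increase over the best value seen so far (no
minimum delta); the plateau counter resets both on improvement and on a
reduction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import confusion, metrics, probabilities_to_mask
from .nn.losses import categorical_crossentropy
from .nn.unet import TrainableModel, compile_model
from .tiling import PatchSet


@dataclass
class TrainingConfig:
    epochs: int = 100
    batch_size: int = 4
    lr0: float = 1e-4
    plateau_factor: float = 0.9
    plateau_patience: int = 10
    min_lr: float = 1e-7
    early_stop_patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.min_lr >= self.lr0:
            raise ValueError("min_lr must be below the initial learning rate")
        if min(self.plateau_patience, self.early_stop_patience) < 1:
            raise ValueError("patiences must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` consecutive epochs
    without improvement of the monitored value (maximized), clamped at
    ``min_lr``. The wait counter resets on improvement and on reduction."""

    def __init__(self, lr0: float, factor: float = 0.9, patience: int = 10,
                 min_lr: float = 1e-7):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = -np.inf
        self.wait = 0

    def step(self, monitored: float) -> float:
        """Record one epoch's monitored value; returns the LR to use next."""
        if monitored > self.best:
            self.best = monitored
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.lr


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int = 15):
        self.patience = patience
        self.best = -np.inf
        self.wait = 0

    def step(self, monitored: float) -> bool:
        if monitored > self.best:
            self.best = monitored
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def _epoch_metrics(conf_sum, loss_sum, n_batches):
    m = metrics(conf_sum)
    return {"loss": loss_sum / max(n_batches, 1), "accuracy": m["accuracy"],
            "iou": m["iou_burnt"]}


def _evaluate_set(trainable: TrainableModel, patches: PatchSet, batch_size: int):
    """Loss/accuracy/burnt-IoU over a patch set, without augmentation."""
    losses, confs = [], None
    for i in range(0, len(patches), batch_size):
        x = patches.images[i:i + batch_size]
        y = patches.masks[i:i + batch_size]
        loss, probs = trainable.evaluate(x, y)
        losses.append(loss * len(x))
        c = confusion(probabilities_to_mask(probs), y[..., 1].astype(np.uint8))
        confs = c if confs is None else _add_conf(confs, c)
    m = metrics(confs)
    return {"loss": float(np.sum(losses) / len(patches)), "accuracy": m["accuracy"],
            "iou": m["iou_burnt"]}


def _add_conf(a, b):
    from .evaluation import ConfusionCounts
    return ConfusionCounts(a.tp + b.tp, a.fp + b.fp, a.fn + b.fn, a.tn + b.tn)


def train(model, train_set: PatchSet, val_set: PatchSet, config: TrainingConfig,
          augment_config=None) -> tuple[dict, pd.DataFrame]:
    """Run the full protocol; returns (best_weights, epoch log).

    The returned weights are those of the epoch with the highest validation
    burnt-class IoU. The log has one row per completed epoch with columns
    mirroring a standard per-epoch training CSV
    (epoch, loss, accuracy, iou, val_loss, val_accuracy, val_iou, lr,
    checkpoint). Deterministic given the config seed.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    trainable = compile_model(model, lr=config.lr0)
    scheduler = PlateauScheduler(config.lr0, config.plateau_factor,
                                 config.plateau_patience, config.min_lr)
    stopper = EarlyStopping(config.early_stop_patience)
    best_iou = -np.inf
    best_weights = model.get_weights()
    rows = []
    from .augment import augment as _augment  # local import to avoid cycle at module load
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_set))
        loss_sum, n_batches, conf_sum = 0.0, 0, None
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            x = train_set.images[idx]
            y = train_set.masks[idx]
            if augment_config is not None:
                pairs = [_augment(xi, yi, augment_config, rng) for xi, yi in zip(x, y)]
                x = np.stack([p[0] for p in pairs])
                y = np.stack([p[1] for p in pairs])
            loss, probs = trainable.train_step(x, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss {loss} at epoch {epoch}")
            loss_sum += loss
            n_batches += 1
            c = confusion(probabilities_to_mask(probs), y[..., 1].astype(np.uint8))
            conf_sum = c if conf_sum is None else _add_conf(conf_sum, c)
        tr = _epoch_metrics(conf_sum, loss_sum, n_batches)
        va = _evaluate_set(trainable, val_set, config.batch_size)
        monitored = va["iou"]
        is_best = monitored > best_iou
        if is_best:
            best_iou = monitored
            best_weights = model.get_weights()
        rows.append({"epoch": epoch, "loss": tr["loss"], "accuracy": tr["accuracy"],
                     "iou": tr["iou"], "val_loss": va["loss"],
                     "val_accuracy": va["accuracy"], "val_iou": va["iou"],
                     "lr": trainable.lr, "checkpoint": is_best})
        trainable.lr = scheduler.step(monitored)
        if stopper.step(monitored):
            break
    log = pd.DataFrame(rows)
    model.set_weights(best_weights)
    return best_weights, log
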