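"""Dice-loss training with Adam and a decaying learning-rate schedule.

The loss is the soft dice complement

    L = 1 - (2*sum(SM*GT) + eps) / (sum(SM) + sum(GT) + eps),

with SM the predicted foreground-probability map and GT the binary ground
truth; on a binarized prediction this equals 1 - DSC.  The learning rate
decays smoothly (per-epoch exponential) from its initial value to
initial/reduction_factor over the scheduled epochs.

Data splitting follows the double cross-validation roles: the training split
fits the weights, the validation split selects the model (the epoch with the
lowest validation loss is kept), and any test split is reserved for the
final report.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .architecture import SegmentationModel
from .nn import Adam
from .nn import autograd as ag

__all__ = ["TrainingSchedule", "dice_loss", "train"]

DICE_SMOOTH = 1e-6


@dataclass
class TrainingSchedule:
    optimizer: str = "adam"
    initial_learning_rate: float = 1e-4
    lr_reduction_factor: float = 10.0
    total_epochs: int = 100
    batch_size: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.initial_learning_rate <= 0 or self.lr_reduction_factor <= 0:
            raise ValueError("learning-rate parameters must be positive")
        if self.total_epochs < 1 or self.batch_size < 1:
            raise ValueError("total_epochs and batch_size must be positive")

    def learning_rate(self, epoch: int) -> float:
        """lr at a given 0-based epoch: exponential decay with endpoints
        lr(0) = initial and lr(last) = initial / reduction_factor."""
        if self.total_epochs == 1:
            return self.initial_learning_rate
        frac = epoch / (self.total_epochs - 1)
        return self.initial_learning_rate * self.lr_reduction_factor ** (-frac)


def dice_loss(sm: np.ndarray, gt: np.ndarray, eps: float = DICE_SMOOTH) -> float:
    """Soft dice loss between a probability map and a binary mask."""
    sm = np.asarray(sm, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if sm.shape != gt.shape:
        raise ValueError(f"shape mismatch: {sm.shape} vs {gt.shape}")
    if sm.min() < 0 or sm.max() > 1:
        raise ValueError("predicted map must lie in [0, 1]")
    inter = float((sm * gt).sum())
    return 1.0 - (2.0 * inter + eps) / (float(sm.sum()) + float(gt.sum()) + eps)


def _as_batches(n, batch_size, order):
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(model: SegmentationModel, dataset, schedule: TrainingSchedule,
          validation=None, verbose: bool = False):
    """Optimize ``model`` on (image, mask) pairs; returns (model, history).

    ``dataset``/``validation``: sequences of (H x W x C image in [0,1],
    H x W binary mask).  ``history`` maps "train_loss" (and "val_loss" when a
    validation split is given) to per-epoch values; with a validation split
    the returned model carries the weights of the best validation epoch.
    Identical data, schedule, and seed reproduce the history exactly.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    images = np.stack([np.asarray(img, dtype=np.float64).transpose(2, 0, 1)
                       for img, _ in dataset])
    masks = np.stack([np.asarray(m, dtype=np.float64) for _, m in dataset])
    rng = np.random.default_rng(schedule.seed)
    optimizer = Adam(model.parameters(), lr=schedule.initial_learning_rate)
    history = {"train_loss": [], "learning_rate": []}
    if validation is not None:
        history["val_loss"] = []
    best = (np.inf, None)

    model.train()
    for epoch in range(schedule.total_epochs):
        lr = schedule.learning_rate(epoch)
        optimizer.lr = lr
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for idx in _as_batches(len(dataset), schedule.batch_size, order):
            x = ag.Tensor(images[idx])
            probs = model(x)
            fg = ag.select_channel(probs, 1)
            loss = ag.soft_dice_loss(fg, masks[idx], eps=DICE_SMOOTH)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite dice loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["learning_rate"].append(lr)
        if validation is not None:
            val = evaluate_loss(model, validation)
            history["val_loss"].append(val)
            if val < best[0]:
                best = (val, copy.deepcopy(model.state_dict()))
        if verbose:  # pragma: no cover - logging only
            msg = f"epoch {epoch + 1}/{schedule.total_epochs} lr={lr:.2e} " \
                  f"loss={history['train_loss'][-1]:.4f}"
            if validation is not None:
                msg += f" val={history['val_loss'][-1]:.4f}"
            print(msg)
    if validation is not None and best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def evaluate_loss(model: SegmentationModel, dataset) -> float:
    """Mean dice loss of the model over a dataset (inference mode)."""
    losses = []
    for img, mask in dataset:
        prob = model.predict_proba(img)
        losses.append(dice_loss(prob, mask))
    return float(np.mean(losses))
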