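"""Patch-level supervised training with a masked pixelwise cross-entropy.

Optimization follows the study protocol for this detector: Adam, batch
size 50, dropout 0.3, up to 120 epochs. Pixels outside the seawater /
red-tide classes contribute nothing to the loss or to validation scores.
The parameters with the best validation F1 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionCounts, metrics
from .nn import Adam
from .nn.autograd import Tensor, masked_softmax_cross_entropy
from .raster_io import PatchDataset

__all__ = ["TrainConfig", "TrainHistory", "masked_loss", "train"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 50
    epochs: int = 120
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    keep_best: bool = True

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int | None = None

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_f1": self.val_f1,
            "best_epoch": self.best_epoch,
        }


def masked_loss(pred: np.ndarray, label: np.ndarray, valid: np.ndarray) -> float:
    """Mean cross-entropy of predicted probabilities over valid pixels.

    pred: (..., K) or (K, ...) class probabilities for K=2 given as
    (P, P, K); label: (P, P) in {0, 1}; valid: (P, P) booleans. Invalid
    pixels contribute nothing; at least one pixel must be valid.
    """
    pred = np.asarray(pred, dtype=np.float64)
    label = np.asarray(label).astype(int)
    valid = np.asarray(valid, dtype=bool)
    if pred.shape[:-1] != label.shape or label.shape != valid.shape:
        raise ValueError("pred/label/valid shapes are inconsistent")
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("masked loss requires at least one valid pixel")
    picked = np.take_along_axis(pred, label[..., None], axis=-1)[..., 0]
    return float(-(np.log(np.clip(picked, 1e-12, None)) * valid).sum() / n_valid)


def _as_batches(n: int, batch_size: int, order: np.ndarray):
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _val_scores(model, x: np.ndarray, y: np.ndarray, valid: np.ndarray,
                batch_size: int) -> tuple[float, float]:
    """Pooled validation loss and F1 over valid pixels."""
    losses, n_valid = [], []
    tp = fp = fn = tn = 0
    for i in range(0, len(x), batch_size):
        xb, yb, vb = x[i : i + batch_size], y[i : i + batch_size], valid[i : i + batch_size]
        p = model.predict_proba(xb)
        picked = np.take_along_axis(p, yb[:, None].astype(int), axis=1)[:, 0]
        nv = int(vb.sum())
        losses.append(float(-(np.log(np.clip(picked, 1e-12, None)) * vb).sum()))
        n_valid.append(nv)
        pred = (p[:, 1] >= 0.5)
        truth = yb.astype(bool)
        tp += int((pred & truth & vb).sum())
        fp += int((pred & ~truth & vb).sum())
        fn += int((~pred & truth & vb).sum())
        tn += int((~pred & ~truth & vb).sum())
    loss = sum(losses) / max(sum(n_valid), 1)
    report = metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    return loss, report.f1


def train(model, dataset: PatchDataset, config: TrainConfig = TrainConfig()):
    """Train a patch model; returns (model, TrainHistory).

    Patches tagged "train" are shuffled each epoch with the config seed;
    patches tagged "test" serve as the validation split. With keep_best the
    parameters of the best-validation-F1 epoch are restored at the end.
    """
    train_split = dataset.subset("train")
    if len(train_split) == 0:
        raise ValueError("training split is empty")
    y_all = train_split.labels[train_split.valid]
    if np.unique(y_all).size < 2:
        raise ValueError("training split must contain both classes among valid pixels")
    val_split = dataset.subset("test")

    x = train_split.features.transpose(0, 3, 1, 2).astype(np.float32)
    y = train_split.labels
    v = train_split.valid
    if val_split is not None and len(val_split):
        xv = val_split.features.transpose(0, 3, 1, 2).astype(np.float32)
        yv, vv = val_split.labels, val_split.valid
    else:
        xv = None

    rng = np.random.default_rng(config.seed)
    if hasattr(model, "reseed_dropout"):
        model.reseed_dropout(int(rng.integers(0, 2**31)))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_f1, best_state = -1.0, None

    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        epoch_losses, epoch_weights = [], []
        for batch in _as_batches(len(x), config.batch_size, order):
            opt.zero_grad()
            logits = model.forward_logits(Tensor(x[batch]), train=True)
            loss = masked_softmax_cross_entropy(logits, y[batch], v[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            epoch_weights.append(int(v[batch].sum()))
        history.train_loss.append(
            float(np.average(epoch_losses, weights=epoch_weights))
        )
        if xv is not None:
            vloss, vf1 = _val_scores(model, xv, yv, vv, config.batch_size)
            history.val_loss.append(vloss)
            history.val_f1.append(vf1)
            if config.keep_best and vf1 > best_f1:
                best_f1 = vf1
                best_state = model.get_state()
                history.best_epoch = epoch
    if best_state is not None:
        model.set_state(best_state)
    return model, history
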