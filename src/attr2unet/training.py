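"""BCE training loop with Adam, plateau learning-rate decay and per-epoch
validation model selection, plus test-set evaluation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import MetricsReport, aggregate_reports, confusion, pr_curve, scalar_metrics
from .network import AttR2UNet
from .nn import autograd as ag
from .nn.optim import Adam
from .records import SliceRecord

__all__ = ["TrainConfig", "TrainHistory", "bce_loss", "train", "evaluate"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 8
    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.5
    lr_patience: int = 5  # epochs without val-DSC improvement before decay
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 1e-5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.adam_beta1 < 1 and 0 < self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmax(self.val_dsc))


def bce_loss(pred, target, clip: float = 1e-7) -> float:
    """Mean binary cross-entropy over all pixels (predictions clipped to
    [clip, 1-clip] so the loss stays finite at saturated outputs)."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if not np.all(np.isin(np.unique(target), (0.0, 1.0))):
        raise ValueError("target must be binary")
    p = np.clip(pred, clip, 1.0 - clip)
    return float(-(target * np.log(p) + (1.0 - target) * np.log1p(-p)).mean())


def _stack(records: Sequence[SliceRecord], dtype) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([r.image for r in records]).astype(dtype)[:, None]
    masks = np.stack([r.mask for r in records]).astype(dtype)[:, None]
    return images, masks


def _predict(model: AttR2UNet, images: np.ndarray, batch_size: int) -> np.ndarray:
    outs = []
    for i in range(0, len(images), batch_size):
        outs.append(model(images[i : i + batch_size]).data)
    return np.concatenate(outs, axis=0)


def _mean_val_dsc(model: AttR2UNet, images, masks, threshold, batch_size) -> float:
    probs = _predict(model, images, batch_size)
    vals = []
    for p, m in zip(probs, masks):
        c = confusion(p[0] >= threshold, m[0] > 0.5)
        vals.append(scalar_metrics(c)["dsc"])
    return float(np.mean(vals))


def train(
    model: AttR2UNet,
    train_set: Sequence[SliceRecord],
    val_set: Sequence[SliceRecord],
    config: TrainConfig,
) -> tuple[AttR2UNet, TrainHistory]:
    """Optimize with Adam/BCE; after every epoch the validation mean DSC is
    measured and the best-epoch parameters are restored at the end."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    dtype = np.dtype(model.config.dtype).type
    x_train, y_train = _stack(train_set, dtype)
    x_val, y_val = _stack(val_set, dtype)

    rng = np.random.default_rng(config.seed)
    model.reset_dropout_rng()
    opt = Adam(
        model.parameters(),
        lr=config.initial_lr,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
        weight_decay=config.weight_decay,
    )
    history = TrainHistory()
    best_dsc, best_state, stall = -1.0, None, 0
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            pred = model(x_train[idx])
            loss = ag.binary_cross_entropy(pred, y_train[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        val_dsc = _mean_val_dsc(model, x_val, y_val, config.threshold, config.batch_size)
        history.train_loss.append(float(np.mean(losses)))
        history.val_dsc.append(val_dsc)
        history.lr.append(opt.lr)
        logger.info(
            "epoch %d lr %.2e train_loss %.4f val_dsc %.4f", epoch, opt.lr, history.train_loss[-1], val_dsc
        )
        if val_dsc > best_dsc:
            best_dsc, best_state, stall = val_dsc, model.state_dict(), 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                opt.lr *= config.lr_decay_factor
                stall = 0
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(
    model: AttR2UNet,
    test_set: Sequence[SliceRecord],
    threshold: float = 0.5,
    batch_size: int = 8,
) -> MetricsReport:
    """Per-slice confusion metrics (mean ± std over slices) at `threshold`,
    plus a pooled-pixel PR curve from the raw probabilities."""
    if len(test_set) == 0:
        raise ValueError("test set must be non-empty")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    dtype = np.dtype(model.config.dtype).type
    images, masks = _stack(test_set, dtype)
    model.eval()
    probs = _predict(model, images, batch_size)
    per_slice: dict[str, list[float]] = {k: [] for k in ("dsc", "jaccard", "precision", "specificity", "sensitivity")}
    for p, m in zip(probs, masks):
        c = confusion(p[0] >= threshold, m[0] > 0.5)
        for k, v in scalar_metrics(c).items():
            per_slice[k].append(v)
    auc = None
    if any(m.sum() > 0 for m in masks):
        auc = pr_curve([p[0] for p in probs], [m[0] > 0.5 for m in masks]).auc
    return aggregate_reports({k: np.asarray(v) for k, v in per_slice.items()}, auc=auc)
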