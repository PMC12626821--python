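"""Training and evaluation drivers.

The training recipe mirrors the study protocol: SGD with momentum 0.9,
initial learning rate 7e-3 with step decay, batch size 8, 180 epochs,
hybrid cross-entropy/focal objective, and on-the-fly flip/crop
augmentation.  Every epoch logs the train loss, validation loss and
validation MIoU; the best-validation-MIoU and last checkpoints are kept.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import nn
from .data import DEFAULT_SCHEMA, LabelSchema, augment
from .losses import LossConfig, hybrid_loss_from_logits
from .metrics import (MetricsReport, confusion_matrix, dice_per_image,
                      roc_auc_ovr, segmentation_metrics)
from .network import HHBSNet, save_checkpoint

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "TrainLog",
    "TrainingDiverged",
    "DataLeakageError",
    "learning_rate_at",
    "train",
    "fit_full_batch",
    "EvaluationResult",
    "evaluate",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


class DataLeakageError(ValueError):
    """Raised when an evaluation set overlaps the training set."""


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 180
    batch_size: int = 8
    momentum: float = 0.9
    initial_lr: float = 7e-3
    lr_decay_factor: float = 0.1
    lr_decay_period: int = 60
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    seed: int = 0
    device: str = "cpu"
    input_size: int = 512
    augment: bool = True
    crop_scale_range: tuple[float, float] = (0.7, 1.0)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be at least 1")
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclasses.dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_loss: float
    val_miou: float


@dataclasses.dataclass
class TrainLog:
    records: list[EpochRecord]
    best_checkpoint: str
    last_checkpoint: str
    config: TrainConfig


def learning_rate_at(cfg: TrainConfig, epoch: int) -> float:
    """Step decay: lr = initial * factor^floor(epoch / period)."""
    return cfg.initial_lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_period)


def _batch_arrays(records, indices, cfg: TrainConfig,
                  rng: np.random.Generator | None):
    images, masks = [], []
    for i in indices:
        img = records[i]["image"]
        msk = records[i]["mask"]
        if rng is not None and cfg.augment:
            img, msk = augment(img, msk, rng,
                               crop_scale_range=cfg.crop_scale_range)
        images.append(np.asarray(img, dtype=np.float64))
        masks.append(np.asarray(msk))
    return np.stack(images), np.stack(masks)


def _validation_pass(model: HHBSNet, records, cfg: TrainConfig) -> tuple[float, float]:
    model.eval()
    k = model.config.num_classes
    cm = np.zeros((k, k), dtype=np.int64)
    losses = []
    for rec in records:
        logits = model.forward(rec["image"][None].astype(np.float64))
        losses.append(hybrid_loss_from_logits(logits, rec["mask"][None],
                                              cfg.loss).data.item())
        pred = logits.data[0].argmax(axis=0)
        cm += confusion_matrix(pred, rec["mask"], k)
    model.train()
    return float(np.mean(losses)), segmentation_metrics(cm).miou


def train(model: HHBSNet, cfg: TrainConfig, train_records, val_records,
          out_dir) -> TrainLog:
    """Run the full training loop; returns the log with checkpoint paths."""
    if not train_records or not val_records:
        raise ValueError("train and validation collections must be nonempty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.SGD(model.parameters(), lr=cfg.initial_lr,
                       momentum=cfg.momentum)
    best_path = out_dir / "best.npz"
    last_path = out_dir / "last.npz"
    curve_path = out_dir / "curves.csv"
    log_path = out_dir / "train.log"
    records: list[EpochRecord] = []
    best_miou = -1.0
    model.train()
    with open(curve_path, "w") as curves, open(log_path, "w") as logf:
        curves.write("epoch,lr,train_loss,val_loss,val_miou\n")
        for epoch in range(cfg.epochs):
            optimizer.lr = learning_rate_at(cfg, epoch)
            order = rng.permutation(len(train_records))
            epoch_losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                images, masks = _batch_arrays(train_records, batch, cfg, rng)
                optimizer.zero_grad()
                logits = model.forward(images)
                loss = hybrid_loss_from_logits(logits, masks, cfg.loss)
                value = loss.data.item()
                if not np.isfinite(value):
                    raise TrainingDiverged(
                        f"non-finite loss {value} at epoch {epoch}")
                loss.backward()
                optimizer.step()
                epoch_losses.append(value)
            val_loss, val_miou = _validation_pass(model, val_records, cfg)
            rec = EpochRecord(epoch=epoch, lr=optimizer.lr,
                              train_loss=float(np.mean(epoch_losses)),
                              val_loss=val_loss, val_miou=val_miou)
            records.append(rec)
            curves.write(f"{rec.epoch},{rec.lr:.6g},{rec.train_loss:.6f},"
                         f"{rec.val_loss:.6f},{rec.val_miou:.6f}\n")
            logf.write(f"epoch {rec.epoch:4d}  lr {rec.lr:.6g}  "
                       f"train {rec.train_loss:.4f}  val {rec.val_loss:.4f}  "
                       f"val_miou {rec.val_miou:.4f}\n")
            save_checkpoint(last_path, model)
            if val_miou > best_miou:
                best_miou = val_miou
                save_checkpoint(best_path, model)
    return TrainLog(records=records, best_checkpoint=str(best_path),
                    last_checkpoint=str(last_path), config=cfg)


def fit_full_batch(model: HHBSNet, images: np.ndarray, masks: np.ndarray,
                   steps: int, lr: float, momentum: float = 0.9,
                   loss_config: LossConfig | None = None) -> list[float]:
    """Plain full-batch gradient descent, no augmentation or bookkeeping.

    Used for capability probes (overfitting a handful of scenes) where
    only the loss trajectory matters.  Returns the per-step losses.
    """
    loss_cfg = loss_config or LossConfig()
    optimizer = nn.SGD(model.parameters(), lr=lr, momentum=momentum)
    model.train()
    losses = []
    for _ in range(steps):
        optimizer.zero_grad()
        logits = model.forward(images)
        loss = hybrid_loss_from_logits(logits, masks, loss_cfg)
        value = loss.data.item()
        if not np.isfinite(value):
            raise TrainingDiverged(f"non-finite loss {value}")
        loss.backward()
        optimizer.step()
        losses.append(value)
    return losses


@dataclasses.dataclass
class EvaluationResult:
    report: MetricsReport
    cm: np.ndarray
    auc: dict[int, float | None]
    hhb_dice: float


def evaluate(model: HHBSNet, records, schema: LabelSchema = DEFAULT_SCHEMA,
             train_basenames=None, allow_overlap: bool = False
             ) -> EvaluationResult:
    """Aggregate one confusion matrix over all pixels and derive metrics.

    Also reports one-vs-rest AUCs from the probability maps and the
    mean per-image Dice of the lesion (HHB) class.  If
    ``train_basenames`` is given, refuses overlapping collections
    unless ``allow_overlap``.
    """
    if not records:
        raise ValueError("evaluation collection is empty")
    if train_basenames is not None and not allow_overlap:
        overlap = {r["basename"] for r in records} & set(train_basenames)
        if overlap:
            raise DataLeakageError(
                f"evaluation items also appear in the training set: "
                f"{sorted(overlap)[:5]}...")
    k = model.config.num_classes
    if k != schema.num_classes:
        raise ValueError(f"model has {k} classes but schema has "
                         f"{schema.num_classes}")
    cm = np.zeros((k, k), dtype=np.int64)
    all_probs, all_refs, dices = [], [], []
    hhb = schema.index("HHB")
    for rec in records:
        probs = model.predict_proba(rec["image"].astype(np.float64))
        pred = probs.argmax(axis=0)
        cm += confusion_matrix(pred, rec["mask"], k)
        dices.append(dice_per_image(pred, rec["mask"], hhb))
        all_probs.append(probs.reshape(k, -1))
        all_refs.append(np.asarray(rec["mask"]).reshape(-1))
    auc = roc_auc_ovr(np.concatenate(all_probs, axis=1),
                      np.concatenate(all_refs))
    return EvaluationResult(report=segmentation_metrics(cm), cm=cm, auc=auc,
                            hhb_dice=float(np.mean(dices)))
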