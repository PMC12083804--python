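"""Seeded training and evaluation pipeline.

Defaults follow the reference fine-tuning settings: batch size 32,
AdamW with learning rate 5e-4 and decoupled weight decay 0.05,
200 epochs, inputs resized to 224x224, constant learning rate.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from . import nn
from .metrics import ConfusionMatrix, confusion_matrix, write_metrics_csv
from .network import (
    NetworkConfig,
    RSCDNet,
    build_rscdnet,
    load_checkpoint,
    save_checkpoint,
)
from .nn import functional as F
from .synthetic_data import SPLITS

__all__ = ["TrainConfig", "RunRecord", "load_split", "train", "evaluate"]


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 200
    optimizer: str = "adamw"
    learning_rate: float = 5e-4
    weight_decay: float = 0.05
    input_size: int = 224
    seed: int = 0
    augment: bool = True
    rotation_deg: float = 15.0
    out_dir: Optional[str] = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.input_size < 16:
            raise ValueError("batch_size, epochs and input_size must be positive")
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("learning_rate and weight_decay must be non-negative")
        if self.optimizer.lower() != "adamw":
            raise ValueError(f"unsupported optimizer: {self.optimizer}")


@dataclass
class RunRecord:
    seed: int
    epochs: list = field(default_factory=list)  # per-epoch dicts
    best_epoch: int = -1
    best_val_accuracy: float = 0.0
    fingerprint: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _environment_fingerprint() -> dict:
    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "machine": platform.machine(),
    }


def load_split(data_root, split: str, input_size: int):
    """Load one split as (X, y, class_names) with X in (N, 3, S, S).

    Images are bilinearly resized to ``input_size`` (plain resize, no
    aspect-preserving crop) and standardized to roughly [-2, 2].
    """
    root = Path(data_root) / split
    if not root.is_dir():
        raise ValueError(f"split directory not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class directories under {root}")
    xs, ys = [], []
    names = tuple(d.name for d in class_dirs)
    for ci, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"empty class directory: {d}")
        for p in files:
            with Image.open(p) as im:
                im = im.convert("RGB").resize((input_size, input_size),
                                              Image.Resampling.BILINEAR)
                arr = np.asarray(im, dtype=np.float64) / 255.0
            xs.append(np.transpose((arr - 0.5) / 0.25, (2, 0, 1)))
            ys.append(ci)
    return np.stack(xs), np.asarray(ys, dtype=np.int64), names


def _augment_batch(x: np.ndarray, rng: np.random.Generator,
                   rotation_deg: float) -> np.ndarray:
    """Train-time flips and small rotations (disabled for val/test)."""
    out = x.copy()
    for i in range(out.shape[0]):
        if rng.random() < 0.5:
            out[i] = out[i, :, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1, :]
        angle = rng.uniform(-rotation_deg, rotation_deg)
        if abs(angle) > 0.5:
            out[i] = ndimage.rotate(out[i], angle, axes=(1, 2), reshape=False,
                                    order=1, mode="nearest")
    return out


def _predict(model: RSCDNet, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    model.eval()
    preds = []
    for i in range(0, x.shape[0], batch_size):
        logits = model(x[i:i + batch_size])
        preds.append(np.argmax(logits, axis=1))
    return np.concatenate(preds)


def train(net_cfg: NetworkConfig, train_cfg: TrainConfig, data_root,
          model: Optional[RSCDNet] = None):
    """Cross-entropy training with seeded order, init and augmentation.

    Returns ``(model, record, best_state)``; the best-validation-accuracy
    checkpoint (ties broken toward the earlier epoch) is also written to
    ``train_cfg.out_dir`` when set.
    """
    x_train, y_train, names = load_split(data_root, "train", train_cfg.input_size)
    x_val, y_val, names_v = load_split(data_root, "val", train_cfg.input_size)
    if names != names_v:
        raise ValueError("train/val class directories disagree")
    if net_cfg.num_classes != len(names):
        raise ValueError(
            f"model expects {net_cfg.num_classes} classes, data has {len(names)}"
        )
    if net_cfg.input_size != train_cfg.input_size:
        raise ValueError("net_cfg.input_size and train_cfg.input_size disagree")

    rng = np.random.default_rng([train_cfg.seed, 0x7E41])
    if model is None:
        model = build_rscdnet(net_cfg, seed=train_cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=train_cfg.learning_rate,
                   weight_decay=train_cfg.weight_decay)
    record = RunRecord(seed=train_cfg.seed, fingerprint=_environment_fingerprint())

    n = x_train.shape[0]
    best_state = None
    for epoch in range(train_cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            xb = x_train[idx]
            if train_cfg.augment:
                xb = _augment_batch(xb, rng, train_cfg.rotation_deg)
            yb = y_train[idx]
            captured = {}

            def closure():
                logits = model(xb)
                captured["logits"] = F._np_value(logits)
                return F.cross_entropy(logits, yb)

            loss, grads = nn.loss_and_gradients(model, closure)
            loss = float(loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // train_cfg.batch_size}: {loss}"
                )
            opt.step(grads)
            losses.append(loss)
            correct += int((np.argmax(captured["logits"], axis=1) == yb).sum())

        train_acc = correct / n
        val_pred = _predict(model, x_val, train_cfg.batch_size)
        val_acc = float((val_pred == y_val).mean())
        record.epochs.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": train_acc,
            "val_accuracy": val_acc,
        })
        if val_acc > record.best_val_accuracy or record.best_epoch < 0:
            record.best_val_accuracy = val_acc
            record.best_epoch = epoch
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    if train_cfg.out_dir:
        out = Path(train_cfg.out_dir)
        save_checkpoint(model, out / "checkpoint.npz", seed=train_cfg.seed,
                        extra={"classes": list(names)})
        record.to_json(out / "run_record.json")
    return model, record, best_state


def evaluate(checkpoint, data_root, split: str = "test",
             out_dir: Optional[str] = None,
             model: Optional[RSCDNet] = None,
             class_names: Optional[Tuple[str, ...]] = None):
    """Deterministic evaluation-mode predictions + metric artifacts.

    Returns ``(ConfusionMatrix, metrics DataFrame)``.
    """
    if split not in SPLITS:
        raise ValueError(f"split must be one of {SPLITS}")
    if model is None:
        model, cfg, _ = load_checkpoint(checkpoint)
    else:
        cfg = model.cfg
    x, y, names = load_split(data_root, split, cfg.input_size)
    if cfg.num_classes != len(names):
        raise ValueError(
            f"checkpoint expects {cfg.num_classes} classes, data has {len(names)}"
        )
    preds = _predict(model, x)
    truth_labels = [names[i] for i in y]
    pred_labels = [names[i] for i in preds]
    cm = confusion_matrix(truth_labels, pred_labels, names)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cm.to_csv(out / "confusion_matrix.csv")
        table = write_metrics_csv(cm, out / "metrics.csv")
    else:
        from .metrics import metrics_table

        table = metrics_table(cm)
    return cm, table
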