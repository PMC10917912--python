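"""Training and evaluation pipeline.

The recipe mirrors standard fine-grained classification practice on
224 x 224 RGB inputs: AdamW (lr 2e-4, weight decay 1e-4), cosine
annealing of the learning rate over the training run, batch size 16, a
stratified 8:2 train/validation split with a fixed seed, and per-channel
normalisation with corpus statistics.  Cross-entropy is applied to the
ensembled prediction only.

The validation share of a class with ``n_c`` items is
``floor((1 - ratio) * n_c)`` computed in decimal arithmetic, so an 8:2
split of class sizes (385, 523, 318, 293) yields validation shares
(77, 104, 63, 58) exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from PIL import Image

from . import nn
from .dataset_info import CORPUS_MEAN, CORPUS_STD
from .heads import predicted_labels
from .metrics import (
    ConfusionMatrix,
    MetricReport,
    PredictionRecord,
    full_report,
    plot_confusion,
    plot_roc,
    write_confusion_csv,
    write_report_json,
    write_roc_csv,
)
from .model import WFPNClassifier, build_model
from .nn import functional as F
from .nn.optim import AdamW, CosineAnnealingLR
from .nn.tensor import Tensor, no_grad
from .synthetic import STAGE_NAMES

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Hyperparameters and preprocessing constants for one training run."""

    learning_rate: float = 2e-4
    weight_decay: float = 1e-4
    epochs: int = 100
    batch_size: int = 16
    image_size: int = 224
    split_ratio: float = 0.8
    seed: int = 0
    eta_min: float = 0.0
    mean: Tuple[float, float, float] = CORPUS_MEAN
    std: Tuple[float, float, float] = CORPUS_STD
    backbone: str = "resnext50_32x4d"
    num_classes: int = 4
    channels: int = 256
    epsilon: float = 1e-4
    reduction: int = 16
    hidden: int = 256

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")
        if min(self.learning_rate, self.weight_decay if self.weight_decay else 1,
               self.batch_size, self.epochs) <= 0:
            raise ValueError("rates and counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mean", "std"):
            if key in known:
                known[key] = tuple(known[key])
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def model_config(self) -> dict:
        return {
            "backbone": self.backbone,
            "neck": {"channels": self.channels, "epsilon": self.epsilon},
            "cbam": {"reduction": self.reduction},
            "head": {"num_classes": self.num_classes, "hidden": self.hidden},
        }


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """In-memory dataset: raw [0,1] images (N,3,H,W), labels, optional paths."""

    images: np.ndarray
    labels: np.ndarray
    paths: List[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels disagree in length")
        if not self.paths:
            self.paths = [f"array:{i}" for i in range(len(self.labels))]

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: Sequence[int]) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(self.images[idx], self.labels[idx], [self.paths[i] for i in idx])

    def num_classes(self) -> int:
        return int(self.labels.max()) + 1


def load_image(path, image_size: int) -> np.ndarray:
    """One PNG/JPEG as a (3, H, W) float array in [0, 1]."""
    with Image.open(path) as im:
        im = im.convert("RGB").resize((image_size, image_size), Image.BILINEAR)
        return np.asarray(im, dtype=np.float64).transpose(2, 0, 1) / 255.0


def load_image_folder(root, image_size: int = 224) -> ArrayDataset:
    """Class-per-folder tree (``root/stage1`` ... ``root/stage4``) -> dataset."""
    root = Path(root)
    images, labels, paths = [], [], []
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class folders under {root}")
    for label, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not files:
            raise ValueError(f"class folder {d} is empty")
        for p in files:
            images.append(load_image(p, image_size))
            labels.append(label)
            paths.append(str(p))
    return ArrayDataset(np.stack(images), np.array(labels, dtype=np.int64), paths)


def normalize(images: np.ndarray, mean: Sequence[float], std: Sequence[float]) -> np.ndarray:
    mean = np.asarray(mean).reshape(1, 3, 1, 1)
    std = np.asarray(std).reshape(1, 3, 1, 1)
    return (images - mean) / std


def dataset_stats(dataset: ArrayDataset) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of the raw images — the ``stats`` subcommand."""
    return dataset.images.mean(axis=(0, 2, 3)), dataset.images.std(axis=(0, 2, 3))


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def stratified_split(
    labels: Sequence[int], ratio: float = 0.8, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-class random split: validation gets floor((1-ratio) * n_c) items.

    Decimal arithmetic keeps the flooring exact (binary floats would turn
    0.2 * 385 into 76.999..., off by one).  Deterministic given ``seed``.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no labels to split")
    rng = np.random.default_rng(seed)
    val_frac = Decimal(1) - Decimal(str(ratio))
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if idx.size == 0:
            raise ValueError(f"class {c} is empty")
        n_val = int(val_frac * idx.size)  # Decimal * int floors via int()
        perm = rng.permutation(idx)
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: WFPNClassifier
    log: List[dict]
    best_state: Dict[str, np.ndarray]
    best_accuracy: float


def _accuracy(model: WFPNClassifier, images: np.ndarray, labels: np.ndarray,
              batch_size: int) -> float:
    model.eval()
    correct = 0
    with no_grad():
        for lo in range(0, len(labels), batch_size):
            logits = model(Tensor(images[lo:lo + batch_size]))
            correct += int((predicted_labels(logits) == labels[lo:lo + batch_size]).sum())
    return correct / len(labels)


def train(
    model: WFPNClassifier,
    train_set: ArrayDataset,
    config: TrainConfig,
    val_set: Optional[ArrayDataset] = None,
    out_dir=None,
) -> TrainResult:
    """Cross-entropy training of the ensembled prediction.

    Logs learning rate, mean loss and train/validation accuracy per
    epoch; keeps the state with the best validation accuracy (train
    accuracy when no validation set is given).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if val_set is not None and len(val_set) == 0:
        raise ValueError("validation set is empty; add images or lower split_ratio")
    x_train = normalize(train_set.images, config.mean, config.std)
    x_val = normalize(val_set.images, config.mean, config.std) if val_set is not None else None
    optimizer = AdamW(
        model.parameters(), lr=config.learning_rate, weight_decay=config.weight_decay
    )
    scheduler = CosineAnnealingLR(optimizer, t_max=config.epochs, eta_min=config.eta_min)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    log: List[dict] = []
    best_state = model.state_dict()
    best_acc = -1.0
    n = len(train_set)
    for epoch in range(config.epochs):
        lr_epoch = scheduler.current_lr
        model.train()
        order = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            logits = model(Tensor(x_train[idx]))
            loss = F.cross_entropy(logits, train_set.labels[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss {loss.item()} at epoch {epoch}, batch {lo // config.batch_size}; "
                    f"lr={lr_epoch:.3g}, batch labels={train_set.labels[idx].tolist()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        train_acc = _accuracy(model, x_train, train_set.labels, config.batch_size)
        row = {
            "epoch": epoch,
            "lr": lr_epoch,
            "loss": float(np.mean(losses)),
            "train_accuracy": train_acc,
        }
        monitor = train_acc
        if x_val is not None:
            val_acc = _accuracy(model, x_val, val_set.labels, config.batch_size)
            row["val_accuracy"] = val_acc
            monitor = val_acc
        if monitor > best_acc:
            best_acc = monitor
            best_state = model.state_dict()
        log.append(row)
        logger.info(
            "epoch %d: lr %.3g loss %.4f train_acc %.3f%s",
            epoch, lr_epoch, row["loss"], train_acc,
            f" val_acc {row['val_accuracy']:.3f}" if "val_accuracy" in row else "",
        )
        scheduler.step()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "train_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[-1].keys()))
            writer.writeheader()
            writer.writerows(log)
        save_checkpoint(model, config, out_dir / "checkpoint_last.npz")
        current = model.state_dict()
        model.load_state_dict(best_state)
        save_checkpoint(model, config, out_dir / "checkpoint_best.npz")
        model.load_state_dict(current)
    return TrainResult(model, log, best_state, best_acc)


# ---------------------------------------------------------------------------
# evaluation and prediction
# ---------------------------------------------------------------------------

def predict_records(
    model: WFPNClassifier, dataset: ArrayDataset, config: TrainConfig
) -> List[PredictionRecord]:
    """Deterministic (eval-mode) per-image class scores for a dataset."""
    x = normalize(dataset.images, config.mean, config.std)
    model.eval()
    records = []
    with no_grad():
        for lo in range(0, len(dataset), config.batch_size):
            logits = model(Tensor(x[lo:lo + config.batch_size])).numpy()
            for i, row in enumerate(logits):
                j = lo + i
                records.append(
                    PredictionRecord.from_scores(row, dataset.labels[j], dataset.paths[j])
                )
    return records


def write_predictions_csv(records: Sequence[PredictionRecord], path) -> None:
    k = len(records[0].scores)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "true", "predicted"] + [f"score_{STAGE_NAMES[i]}" for i in range(k)])
        for r in records:
            writer.writerow([r.path, r.true, r.predicted] + [f"{s:.10g}" for s in r.scores])


def read_predictions_csv(path) -> List[PredictionRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        k = len(header) - 3
        for row in reader:
            records.append(
                PredictionRecord(
                    scores=np.array([float(v) for v in row[3:3 + k]]),
                    predicted=int(row[2]),
                    true=int(row[1]),
                    path=row[0],
                )
            )
    return records


def evaluate(
    model: WFPNClassifier,
    dataset: ArrayDataset,
    config: TrainConfig,
    out_dir=None,
    plots: bool = False,
) -> Tuple[MetricReport, ConfusionMatrix, List[PredictionRecord]]:
    """Full metric report on a dataset; optionally writes all artifacts."""
    if len(dataset) == 0:
        raise ValueError("empty evaluation set")
    if dataset.num_classes() > model.num_classes:
        raise ValueError(
            f"dataset has labels up to {dataset.num_classes() - 1} but the model "
            f"predicts {model.num_classes} classes"
        )
    records = predict_records(model, dataset, config)
    report, cm = full_report(records, model.num_classes)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_predictions_csv(records, out_dir / "predictions.csv")
        write_report_json(report, out_dir / "metrics.json")
        write_confusion_csv(cm, out_dir / "confusion.csv")
        write_confusion_csv(cm, out_dir / "confusion_normalized.csv", normalized=True)
        write_roc_csv(report, out_dir / "roc")
        if plots:
            plot_roc(report, out_dir / "roc.png")
            plot_confusion(cm, out_dir / "confusion.png")
    return report, cm, records


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: WFPNClassifier, config: TrainConfig, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> Tuple[WFPNClassifier, TrainConfig]:
    data = dict(np.load(path))
    cfg_raw = json.loads(data.pop("__config__").tobytes().decode())
    for key in ("mean", "std"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = TrainConfig(**cfg_raw)
    nn.manual_seed(config.seed)
    model = build_model(config.model_config())
    model.load_state_dict(data)
    return model, config


def build_seeded_model(config: TrainConfig) -> WFPNClassifier:
    """Model with parameter initialisation fixed by ``config.seed``."""
    nn.manual_seed(config.seed)
    return build_model(config.model_config())
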