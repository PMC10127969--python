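"""Training, evaluation and model-comparison pipeline.

Implements the training recipe used for the segmentation benchmarks: Adam at
initial learning rate 1e-3 cosine-annealed per epoch to 1e-5, batch size 4,
flip/crop augmentation, the 0.5*BCE + Dice joint loss, per-epoch validation,
and retention of the checkpoint with the best validation IOU.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from . import autograd as ag
from . import data_synth, loss_metrics, topsis
from .loss_metrics import LossConfig, MetricsReport
from .network import MBSNet, MBSNetConfig, load_checkpoint, save_checkpoint
from .optim import Adam, cosine_annealing_lr


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    lr_init: float = 1e-3
    lr_min: float = 1e-5
    epochs: int = 100
    loss: LossConfig = field(default_factory=LossConfig)
    selection_metric: str = "IOU"          # or "F1"
    augment: bool = True
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    crop_fraction: tuple = (0.8, 1.0)
    input_size: int | None = None          # defaults to the network input size
    seed: int = 0

    def __post_init__(self):
        if self.lr_min >= self.lr_init:
            raise ValueError("lr_min must be below lr_init")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.selection_metric not in ("IOU", "F1"):
            raise ValueError("selection_metric must be IOU or F1")


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_iou: list = field(default_factory=list)
    val_f1: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = -1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _normalization(data_root) -> tuple:
    manifest = os.path.join(os.fspath(data_root), "manifest.json")
    if os.path.exists(manifest):
        import json
        with open(manifest) as fh:
            stats = json.load(fh).get("normalization")
        if stats:
            return tuple(stats["mean"]), tuple(stats["std"])
    return (0.5, 0.5, 0.5), (0.25, 0.25, 0.25)


def _prepare(images, masks, size, mean, std):
    xs, ys = [], []
    for img, msk in zip(images, masks):
        x, y = data_synth.preprocess(img, msk, size=size, mean=mean, std=std)
        xs.append(x)
        ys.append(y)
    return np.stack(xs), np.stack(ys)


def _predict_probs(net: MBSNet, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Sigmoid probabilities for a stack of preprocessed images, batched."""
    outs = []
    was_training = net.training
    net.eval()
    try:
        with ag.no_grad():
            for lo in range(0, len(x), batch_size):
                logits = net(x[lo:lo + batch_size])
                outs.append(ag.sigmoid_np(logits.data))
    finally:
        net.train(was_training)
    return np.concatenate(outs, axis=0)


def evaluate_arrays(net: MBSNet, x: np.ndarray, y: np.ndarray,
                    names=None) -> MetricsReport:
    probs = _predict_probs(net, x)
    preds = [loss_metrics.binarize(p[0]) for p in probs]
    gts = [m[0].astype(np.uint8) for m in y]
    return loss_metrics.evaluate_dataset(preds, gts, names=names)


def train(net_cfg: MBSNetConfig, train_cfg: TrainConfig, data_root,
          out_dir) -> tuple:
    """Train on ``<data_root>/train``, validate per epoch on ``<data_root>/val``.

    Returns (checkpoint_path, TrainHistory); the checkpoint holds the weights
    of the epoch with the best validation selection metric.
    """
    os.makedirs(out_dir, exist_ok=True)
    size = train_cfg.input_size or net_cfg.input_size[0]
    mean, std = _normalization(data_root)

    tr_images, tr_masks, _ = data_synth.load_split(data_root, "train")
    va_images, va_masks, va_names = data_synth.load_split(data_root, "val")
    xv, yv = _prepare(va_images, va_masks, size, mean, std)

    net = MBSNet(net_cfg)
    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(net.parameters(), lr=train_cfg.lr_init)
    aug_spec = data_synth.AugmentationSpec(
        hflip_prob=train_cfg.hflip_prob if train_cfg.augment else 0.0,
        vflip_prob=train_cfg.vflip_prob if train_cfg.augment else 0.0,
        crop_fraction=train_cfg.crop_fraction if train_cfg.augment else (1.0, 1.0),
        seed=train_cfg.seed)

    history = TrainHistory()
    ckpt_path = os.path.join(out_dir, "best.npz")
    n_train = len(tr_images)
    aug_counter = 0

    for epoch in range(train_cfg.epochs):
        lr = cosine_annealing_lr(epoch, train_cfg.epochs,
                                 train_cfg.lr_init, train_cfg.lr_min)
        optimizer.lr = lr
        order = rng.permutation(n_train)
        net.train()
        losses = []
        for lo in range(0, n_train, train_cfg.batch_size):
            batch = order[lo:lo + train_cfg.batch_size]
            imgs, msks = [], []
            for idx in batch:
                img, msk = data_synth.augment(tr_images[idx], tr_masks[idx],
                                              aug_spec, seed=aug_counter)
                aug_counter += 1
                imgs.append(img)
                msks.append(msk)
            xb, yb = _prepare(imgs, msks, size, mean, std)
            optimizer.zero_grad()
            logits = net(xb)
            loss = loss_metrics.bce_dice_loss(logits, yb, train_cfg.loss)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            losses.append(loss.item())

        # validation: one forward pass yields both the loss and the metrics
        with ag.no_grad():
            net.eval()
            val_losses = []
            probs = []
            for lo in range(0, len(xv), train_cfg.batch_size):
                logits = net(xv[lo:lo + train_cfg.batch_size])
                val_losses.append(loss_metrics.bce_dice_loss(
                    logits, yv[lo:lo + train_cfg.batch_size],
                    train_cfg.loss).item())
                probs.append(ag.sigmoid_np(logits.data))
        probs = np.concatenate(probs, axis=0)
        report = loss_metrics.evaluate_dataset(
            [loss_metrics.binarize(p[0]) for p in probs],
            [m[0].astype(np.uint8) for m in yv], names=va_names)
        mean_metrics = report.mean

        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(np.mean(val_losses)))
        history.val_iou.append(mean_metrics["IOU"])
        history.val_f1.append(mean_metrics["F1"])
        history.lr.append(float(lr))
        selected = mean_metrics[train_cfg.selection_metric]
        if selected > history.best_metric:
            history.best_metric = float(selected)
            history.best_epoch = epoch
            save_checkpoint(net, ckpt_path, extra={
                "epoch": epoch, "val_metrics": mean_metrics,
                "mean": list(mean), "std": list(std)})

    return ckpt_path, history


def evaluate_checkpoint(ckpt_path, data_root, split: str, out_dir=None):
    """Deterministic evaluation of a saved checkpoint on one dataset split.

    Writes per-image metrics CSV and predicted masks as PNG when ``out_dir``
    is given.  Returns (MetricsReport, n_failures).
    """
    net, extra = load_checkpoint(ckpt_path)
    mean = tuple(extra.get("mean", (0.5, 0.5, 0.5)))
    std = tuple(extra.get("std", (0.25, 0.25, 0.25)))
    size = net.config.input_size[0]
    images, masks, names = data_synth.load_split(data_root, split)
    failures = 0
    preds, gts, kept = [], [], []
    for img, msk, name in zip(images, masks, names):
        if img.shape[:2] != msk.shape[:2]:
            failures += 1
            continue
        x, y = data_synth.preprocess(img, msk, size=size, mean=mean, std=std)
        prob = _predict_probs(net, x[None])[0, 0]
        preds.append(loss_metrics.binarize(prob))
        gts.append(y[0].astype(np.uint8))
        kept.append(name)
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            Image.fromarray((loss_metrics.binarize(prob) * 255).astype(np.uint8),
                            mode="L").save(os.path.join(out_dir, f"pred_{name}"))
    if not preds:
        raise ValueError(f"no evaluable image/mask pairs in split {split!r}")
    report = loss_metrics.evaluate_dataset(preds, gts, names=kept)
    if out_dir is not None:
        report.to_csv(os.path.join(out_dir, f"metrics_{split}.csv"))
    return report, failures


def report_comparison(metric_tables: dict) -> tuple:
    """TOPSIS scores per dataset plus the cross-dataset average-rank table.

    ``metric_tables`` maps dataset name -> DataFrame indexed by model with
    columns F1/IOU/Gmean (at least two models, identical across datasets).
    """
    if not metric_tables:
        raise ValueError("no metric tables given")
    scores, ranks = {}, {}
    model_set = None
    for name, table in metric_tables.items():
        if len(table) < 2:
            raise ValueError("model comparison needs at least 2 models")
        if model_set is None:
            model_set = set(table.index)
        elif set(table.index) != model_set:
            raise ValueError(f"inconsistent model set in dataset {name!r}")
        result = topsis.topsis_scores(topsis.DecisionMatrix(table))
        scores[name] = result.scores
        ranks[name] = result.ranks
    return scores, topsis.average_rank_table(ranks)
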