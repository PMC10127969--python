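"""Compound segmentation loss and evaluation metrics.

Training uses the joint objective

    L = 0.5 * BCE(sigmoid(logits), target) + Dice(sigmoid(logits), target)

with the Dice term 1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps).
Evaluation reports IOU (Jaccard), F1 (Dice), precision, recall, specificity
and the geometric mean of sensitivity and specificity, each on a 0-100 scale,
from exact per-image confusion counts.  Dataset values are unweighted means
over images (macro averaging); pooled-pixel (micro) values are also computed
for reference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag

METRIC_COLUMNS = ("IOU", "F1", "Precision", "Recall", "Specificity", "Gmean")


@dataclass(frozen=True)
class LossConfig:
    bce_weight: float = 0.5
    dice_weight: float = 1.0
    dice_smooth: float = 1.0

    def __post_init__(self):
        if self.bce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def bce_dice_loss(logits, target, cfg: LossConfig = LossConfig()) -> ag.Tensor:
    """Joint BCE + Dice loss on logits; target must be binary {0, 1}.

    BCE is evaluated in the numerically stable logit form
    mean(softplus(z) - z*t); Dice uses probabilities p = sigmoid(z).
    """
    logits = ag.as_tensor(logits)
    target = ag.as_tensor(target)
    if logits.shape != target.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {target.shape}")
    tdat = target.data
    if not np.all((tdat == 0) | (tdat == 1)):
        raise ValueError("target must be binary {0, 1}")

    bce = ag.tmean(ag.add(ag.softplus(logits), ag.mul(ag.mul(logits, target), -1.0)))
    p = ag.sigmoid(logits)
    eps = cfg.dice_smooth
    num = ag.tsum(ag.mul(p, target)) * 2.0 + eps
    den = ag.tsum(p) + float(tdat.sum()) + eps
    dice = 1.0 - num / den
    return bce * cfg.bce_weight + dice * cfg.dice_weight


def binarize(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities to a {0, 1} uint8 mask; p == threshold maps to 1."""
    p = np.asarray(probabilities)
    return (p >= threshold).astype(np.uint8)


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred.astype(bool)
    g = gt.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_counts(c: ConfusionCounts) -> dict:
    """IOU, F1, precision, recall, specificity, G-mean on the 0-100 scale.

    Degenerate conventions: if both ground truth and prediction are empty all
    metrics are 100 (flagged via 'empty_pair'); an empty ground truth with a
    non-empty prediction scores 0 on the foreground metrics.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    if tp + fn == 0 and tp + fp == 0:   # nothing to find, nothing predicted
        return {k: 100.0 for k in METRIC_COLUMNS} | {"empty_pair": True}
    iou = 100.0 * tp / (tp + fp + fn) if tp + fp + fn else 100.0
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    specificity = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    gmean = float(np.sqrt(recall * specificity))
    return {"IOU": iou, "F1": f1, "Precision": precision, "Recall": recall,
            "Specificity": specificity, "Gmean": gmean, "empty_pair": False}


@dataclass
class MetricsReport:
    per_image: list = field(default_factory=list)   # list of metric dicts
    names: list = field(default_factory=list)

    @property
    def mean(self) -> dict:
        if not self.per_image:
            raise ValueError("empty report")
        return {k: float(np.mean([m[k] for m in self.per_image]))
                for k in METRIC_COLUMNS}

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", *METRIC_COLUMNS])
            for name, m in zip(self.names, self.per_image):
                writer.writerow([name] + [f"{m[k]:.4f}" for k in METRIC_COLUMNS])
            mean = self.mean
            writer.writerow(["MEAN"] + [f"{mean[k]:.4f}" for k in METRIC_COLUMNS])


def evaluate_dataset(predictions, ground_truths, names=None,
                     micro: bool = False) -> MetricsReport | tuple:
    """Per-image metrics averaged over a paired list of binary masks.

    With ``micro=True`` additionally returns the pooled-pixel metrics
    computed from summed confusion counts.
    """
    predictions = list(predictions)
    ground_truths = list(ground_truths)
    if not predictions:
        raise ValueError("empty prediction list")
    if len(predictions) != len(ground_truths):
        raise ValueError("prediction/ground-truth length mismatch")
    names = list(names) if names is not None else [
        f"img{i:04d}" for i in range(len(predictions))]
    report = MetricsReport()
    totals = np.zeros(4, dtype=np.int64)
    for name, pred, gt in zip(names, predictions, ground_truths):
        c = confusion_counts(pred, gt)
        totals += (c.tp, c.fp, c.tn, c.fn)
        report.per_image.append(metrics_from_counts(c))
        report.names.append(name)
    if micro:
        pooled = metrics_from_counts(
            ConfusionCounts(tp=int(totals[0]), fp=int(totals[1]),
                            tn=int(totals[2]), fn=int(totals[3])))
        return report, pooled
    return report
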