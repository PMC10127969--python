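"""Classic TOPSIS multi-criteria ranking of segmentation models.

Given an m x n decision matrix (models x benefit criteria, here F1 / IOU /
G-mean), each column is vector-normalized (divided by its Euclidean norm) and
weighted; the ideal point takes the per-column maximum and the anti-ideal the
minimum; each model is scored by its relative closeness d- / (d+ + d-) to the
ideal, in [0, 1].  Models are ranked by descending score with competition
ranking (ties share the smaller rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Published per-dataset benchmark metrics (F1 / IOU / G-mean, percent) of
#: five segmentation models on five public medical segmentation datasets,
#: with the published TOPSIS scores alongside.
PUBLISHED_MODELS = ("UNet", "AttU-Net", "UNet++", "UNeXt", "MBSNet")
PUBLISHED_BENCHMARKS = {
    "ISIC2018": {
        "UNet": (87.21, 79.15, 92.54), "AttU-Net": (85.69, 76.95, 92.27),
        "UNet++": (83.04, 73.95, 90.08), "UNeXt": (88.71, 81.22, 93.7),
        "MBSNet": (87.76, 80.17, 92.99)},
    "Kvasir": {
        "UNet": (80.9, 71.99, 89.56), "AttU-Net": (79.29, 69.73, 89.27),
        "UNet++": (78.73, 69.26, 88.49), "UNeXt": (80.79, 72.5, 88.6),
        "MBSNet": (85.29, 77.66, 92.1)},
    "BUSI": {
        "UNet": (63.68, 53.12, 79.92), "AttU-Net": (66.93, 56.67, 82.51),
        "UNet++": (67.7, 57.4, 80.93), "UNeXt": (65.94, 55.22, 79.0),
        "MBSNet": (72.81, 63.21, 82.16)},
    "COVID-19": {
        "UNet": (76.78, 65.93, 89.06), "AttU-Net": (77.01, 66.06, 89.54),
        "UNet++": (68.61, 56.37, 84.88), "UNeXt": (75.69, 64.91, 87.26),
        "MBSNet": (76.25, 65.13, 89.59)},
    "LGG": {
        "UNet": (69.03, 59.55, 79.06), "AttU-Net": (63.26, 54.47, 72.4),
        "UNet++": (68.85, 58.37, 78.97), "UNeXt": (69.71, 59.59, 79.84),
        "MBSNet": (69.57, 60.23, 79.1)},
}
PUBLISHED_TOPSIS_SCORES = {
    "ISIC2018": {"UNet": 0.23829325, "AttU-Net": 0.14954534, "UNet++": 0.0,
                 "UNeXt": 0.33225513, "MBSNet": 0.27990629},
    "Kvasir": {"UNet": 0.18503661, "AttU-Net": 0.04927065, "UNet++": 0.0,
               "UNeXt": 0.19576564, "MBSNet": 0.5699271},
    "BUSI": {"UNet": 0.02332205, "AttU-Net": 0.18599036, "UNet++": 0.210357,
             "UNeXt": 0.10551958, "MBSNet": 0.47481101},
    "COVID-19": {"UNet": 0.26129017, "AttU-Net": 0.27014396, "UNet++": 0.0,
                 "UNeXt": 0.2220694, "MBSNet": 0.24649646},
    "LGG": {"UNet": 0.25013003, "AttU-Net": 0.0, "UNet++": 0.22191493,
            "UNeXt": 0.26303922, "MBSNet": 0.26491581},
}


def published_benchmark_matrix(dataset: str) -> pd.DataFrame:
    """Decision matrix (models x F1/IOU/Gmean) for one published dataset."""
    rows = PUBLISHED_BENCHMARKS[dataset]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["F1", "IOU", "Gmean"])


@dataclass
class DecisionMatrix:
    """Models x criteria table with benefit weights summing to 1."""

    values: pd.DataFrame
    weights: np.ndarray | None = None
    benefit: np.ndarray | None = None

    def __post_init__(self):
        self.values = pd.DataFrame(self.values).astype(float)
        m, n = self.values.shape
        if m < 2 or n < 1:
            raise ValueError("decision matrix needs at least 2 rows and 1 column")
        if (self.values.values < 0).any():
            raise ValueError("criteria values must be non-negative")
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must have one entry per criterion and sum to 1")
        if self.benefit is None:
            self.benefit = np.ones(n, dtype=bool)
        self.benefit = np.asarray(self.benefit, dtype=bool)
        norms = np.linalg.norm(self.values.values, axis=0)
        if np.any(norms == 0):
            raise ValueError("decision matrix has an all-zero column")

    @staticmethod
    def from_csv(path) -> "DecisionMatrix":
        df = pd.read_csv(path, index_col=0)
        return DecisionMatrix(df)


@dataclass
class TopsisResult:
    scores: pd.Series
    ranks: pd.Series
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "rank": self.ranks})


def topsis_scores(dm: DecisionMatrix) -> TopsisResult:
    """Relative-closeness scores and competition ranks for a decision matrix."""
    v = dm.values.values
    norm = v / np.linalg.norm(v, axis=0)
    weighted = norm * dm.weights
    ideal = np.where(dm.benefit, weighted.max(axis=0), weighted.min(axis=0))
    anti = np.where(dm.benefit, weighted.min(axis=0), weighted.max(axis=0))
    d_plus = np.linalg.norm(weighted - ideal, axis=1)
    d_minus = np.linalg.norm(weighted - anti, axis=1)
    denom = d_plus + d_minus
    degenerate = bool(np.all(denom == 0))
    if degenerate:
        warnings.warn("all alternatives identical; scores set to 0.5")
        scores = np.full(len(v), 0.5)
    else:
        scores = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 0.5)
    scores = pd.Series(scores, index=dm.values.index, name="score")
    return TopsisResult(scores=scores, ranks=rank_from_scores(scores),
                        degenerate=degenerate)


def rank_from_scores(scores) -> pd.Series:
    """Descending competition ranking; ties share the smaller rank."""
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s.values).all():
        raise ValueError("scores must be finite")
    ranks = s.rank(method="min", ascending=False).astype(int)
    return ranks.rename("rank")


def average_rank_table(per_dataset_ranks: dict) -> pd.DataFrame:
    """Combine per-dataset rank series into a table with a mean column.

    ``per_dataset_ranks`` maps dataset name -> Series indexed by model; all
    datasets must cover the identical model set.
    """
    if not per_dataset_ranks:
        raise ValueError("no rank tables given")
    frames = {}
    model_sets = None
    for name, ranks in per_dataset_ranks.items():
        s = pd.Series(ranks)
        if model_sets is None:
            model_sets = set(s.index)
        elif set(s.index) != model_sets:
            raise ValueError(f"model set mismatch in dataset {name!r}")
        frames[name] = s
    table = pd.DataFrame(frames)
    table["Average"] = table.mean(axis=1)
    return table
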