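"""Confusion-matrix metrics, mask-overlap metrics and the k-fold harness.

Metrics with a zero denominator are reported as ``None`` (explicit
"undefined"), never silently 0 — this matters for tiny folds.  All metrics
are fractions; display layers format percents.

The stratified k-fold harness enforces a cross-modality leakage rule: when
pseudo-modality scans are present they may appear only in training splits;
validation and test folds contain real (CT) scans exclusively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .synthetic_data import LabeledScan

__all__ = [
    "ConfusionCounts",
    "confusion",
    "metrics",
    "dice_iou",
    "stratified_kfold",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one sample required")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    predicted: Sequence, truth: Sequence, positive
) -> ConfusionCounts:
    """Tally a 2x2 confusion table against the given positive class."""
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    tp = sum(1 for p, t in zip(predicted, truth) if p == positive and t == positive)
    fp = sum(1 for p, t in zip(predicted, truth) if p == positive and t != positive)
    fn = sum(1 for p, t in zip(predicted, truth) if p != positive and t == positive)
    tn = len(truth) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Standard binary-classification metric set from confusion counts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = (
        _safe_div(2 * precision * sensitivity, precision + sensitivity)
        if precision is not None and sensitivity is not None
        and (precision + sensitivity) > 0
        else None
    )
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    return {
        "accuracy": (tp + tn) / c.total,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "npv": _safe_div(tn, tn + fn),
        "mcc": mcc,
        "fpr": 1.0 - specificity if specificity is not None else None,
        "fnr": 1.0 - sensitivity if sensitivity is not None else None,
    }


def dice_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[float, float]:
    """(Dice, IoU) overlap between two binary masks.

    Both-empty masks are defined as perfect agreement (1, 1).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    inter = float(np.logical_and(a, b).sum())
    sa, sb = float(a.sum()), float(b.sum())
    if sa + sb == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / (sa + sb)
    union = sa + sb - inter
    iou = inter / union if union > 0 else 1.0
    return dice, iou


def stratified_kfold(
    dataset: Sequence[LabeledScan],
    k: int = 5,
    seed: int = 0,
) -> list[dict[str, list[int]]]:
    """Stratified folds over the real (CT) scans with a leakage rule.

    Returns k folds, each ``{"train": [...], "eval": [...]}`` of dataset
    indices.  Real scans are stratified by label into k disjoint eval folds;
    pseudo-modality scans are appended to every training split and never
    appear in an eval fold.
    """
    real_idx = [i for i, s in enumerate(dataset) if s.modality == "ct"]
    pseudo_idx = [i for i, s in enumerate(dataset) if s.modality != "ct"]
    labels = np.array([dataset[i].label for i in real_idx])
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} real scans; cannot make {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    real_idx_arr = np.array(real_idx)
    folds = []
    for train_pos, eval_pos in skf.split(real_idx_arr, labels):
        folds.append(
            {
                "train": sorted(real_idx_arr[train_pos].tolist() + pseudo_idx),
                "eval": sorted(real_idx_arr[eval_pos].tolist()),
            }
        )
    return folds


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Simple percentile bootstrap interval for the mean of ``values``."""
    rng = np.random.default_rng(seed)
    vals = np.asarray(values, dtype=float)
    means = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(means, lo)), float(np.quantile(means, 1.0 - lo))
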