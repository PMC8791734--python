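"""Compound segmentation loss (BCE + Dice) and the pixelwise metric suite.

Training minimizes  L = alpha1 * L_BCE + alpha2 * L_Dice  with
alpha1 = alpha2 = 0.5 by default: the pixel-averaged binary cross-entropy keeps
gradients stable while the Dice term counteracts the foreground/background
imbalance of small tumor targets.  Evaluation reports Accuracy, Precision,
Recall, F1, IOU and DSC from a pixel confusion matrix; DSC and IOU obey
DSC = 2*IOU / (1 + IOU).

Numpy implementations serve reporting; ``*_t`` variants operate on
:class:`osteoseg.nn.Tensor` and are what the trainers differentiate through.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "EPS",
    "LossConfig",
    "ConfusionCounts",
    "MetricReport",
    "bce_pixel_loss",
    "dice_loss",
    "total_loss",
    "bce_pixel_loss_t",
    "dice_loss_t",
    "total_loss_t",
    "confusion",
    "metric_report",
    "evaluate_masks",
]

EPS = 1e-7  # probability clipping bound


@dataclass
class LossConfig:
    alpha1: float = 0.5  # BCE weight
    alpha2: float = 0.5  # Dice weight
    smooth_eps: float = 1e-6

    def validate(self) -> None:
        if self.alpha1 < 0 or self.alpha2 < 0:
            raise ValueError("loss weights must be non-negative")
        if not math.isclose(self.alpha1 + self.alpha2, 1.0, abs_tol=1e-9):
            raise ValueError("alpha1 + alpha2 must equal 1")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    Acc: float
    Pre: float
    Re: float
    F1: float
    IOU: float
    DSC: float
    undefined: tuple = ()


# -- losses (numpy) ---------------------------------------------------------

def bce_pixel_loss(prob_map: np.ndarray, gt_mask: np.ndarray) -> float:
    p = np.clip(np.asarray(prob_map, dtype=float), EPS, 1.0 - EPS)
    y = np.asarray(gt_mask, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probability map and mask shapes differ")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_loss(pred_region: np.ndarray, gt_region: np.ndarray, smooth_eps: float = 1e-6) -> float:
    """1 - 2|GT ∩ Pos| / (|GT| + |Pos|); soft masks use sums of products."""
    p = np.asarray(pred_region, dtype=float)
    y = np.asarray(gt_region, dtype=float)
    if p.shape != y.shape:
        raise ValueError("shapes differ")
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum())
    if denom == 0 and smooth_eps == 0:
        warnings.warn("both regions empty: Dice loss defined as 0", stacklevel=2)
        return 0.0
    return 1.0 - 2.0 * inter / (denom + smooth_eps)


def total_loss(prob_map: np.ndarray, gt_mask: np.ndarray, cfg: LossConfig | None = None) -> float:
    cfg = cfg or LossConfig()
    cfg.validate()
    return cfg.alpha1 * bce_pixel_loss(prob_map, gt_mask) + cfg.alpha2 * dice_loss(
        prob_map, gt_mask, cfg.smooth_eps
    )


# -- losses (autodiff) ------------------------------------------------------

def bce_pixel_loss_t(prob: Tensor, gt_mask: np.ndarray) -> Tensor:
    y = np.asarray(gt_mask, dtype=float)
    p = prob.clip(EPS, 1.0 - EPS)
    return -(
        Tensor(y) * p.log() + Tensor(1.0 - y) * (Tensor(np.ones_like(y)) - p).log()
    ).mean()


def dice_loss_t(prob: Tensor, gt_mask: np.ndarray, smooth_eps: float = 1e-6) -> Tensor:
    y = np.asarray(gt_mask, dtype=float)
    inter = (prob * Tensor(y)).sum()
    denom = prob.sum() + Tensor(y.sum())
    return 1.0 - (2.0 * inter) / (denom + smooth_eps)


def total_loss_t(prob: Tensor, gt_mask: np.ndarray, cfg: LossConfig | None = None) -> Tensor:
    cfg = cfg or LossConfig()
    cfg.validate()
    return cfg.alpha1 * bce_pixel_loss_t(prob, gt_mask) + cfg.alpha2 * dice_loss_t(
        prob, gt_mask, cfg.smooth_eps
    )


# -- metrics ----------------------------------------------------------------

def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray, region=None) -> ConfusionCounts:
    """Pixel confusion counts, optionally restricted to a CredibleRegion."""
    p = np.asarray(pred_mask).astype(bool)
    y = np.asarray(gt_mask).astype(bool)
    if p.shape != y.shape:
        raise ValueError("shapes differ")
    if region is not None:
        sl = (slice(region.min_y, region.max_y + 1), slice(region.min_x, region.max_x + 1))
        p, y = p[sl], y[sl]
    return ConfusionCounts(
        TP=int(np.sum(p & y)),
        TN=int(np.sum(~p & ~y)),
        FP=int(np.sum(p & ~y)),
        FN=int(np.sum(~p & y)),
    )


def metric_report(counts: ConfusionCounts) -> MetricReport:
    """Acc/Pre/Re/F1 from counts, IOU and DSC from the same overlap algebra.

    A metric whose denominator is zero is reported as NaN and listed in
    ``undefined`` rather than raising.
    """
    undef = []

    def _ratio(num, den, name):
        if den == 0:
            undef.append(name)
            return float("nan")
        return num / den

    acc = _ratio(counts.TP + counts.TN, counts.total, "Acc")
    pre = _ratio(counts.TP, counts.TP + counts.FP, "Pre")
    re = _ratio(counts.TP, counts.TP + counts.FN, "Re")
    if math.isnan(pre) or math.isnan(re) or pre + re == 0:
        undef.append("F1")
        f1 = float("nan")
    else:
        f1 = 2.0 * pre * re / (pre + re)
    iou = _ratio(counts.TP, counts.TP + counts.FP + counts.FN, "IOU")
    dsc = _ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN, "DSC")
    return MetricReport(Acc=acc, Pre=pre, Re=re, F1=f1, IOU=iou, DSC=dsc,
                        undefined=tuple(undef))


def evaluate_masks(pred_mask: np.ndarray, gt_mask: np.ndarray, region=None) -> MetricReport:
    return metric_report(confusion(pred_mask, gt_mask, region))
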