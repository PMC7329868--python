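"""Losses and evaluation metrics for voxel-wise segmentation.

The training loss is a weighted combination of the smoothed Tanimoto loss
and categorical crossentropy,

    L = alpha * L_Tanimoto + beta * L_CE,      alpha = 0.6, beta = 0.4

with the per-class Tanimoto loss

    L_c = 1 - (Y_hat.Y + s) / (|Y_hat|^2 + |Y|^2 - Y_hat.Y + s),   s = 1e-5

averaged over classes; treating each class independently makes it suitable
for the heavy class imbalance of organ/tumour segmentation, and the smooth
factor s defuses the empty-class case (0/0 -> loss 0).  Evaluation uses the
Dice overlap 2|A.B| / (|A|^2 + |B|^2) per volume, aggregated as mean +/- std
over volumes and cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LabelVolume

__all__ = [
    "LossConfig",
    "DiceReport",
    "tanimoto_loss",
    "tanimoto_loss_per_class",
    "categorical_crossentropy",
    "combined_loss",
    "combined_loss_grad",
    "dice_score",
    "aggregate_dice",
]

CE_EPSILON = 1e-12  # log-stability clamp on predicted probabilities


@dataclass(frozen=True)
class LossConfig:
    """Weights of the compound loss and the Tanimoto smoothing constant."""

    alpha: float = 0.6
    beta: float = 0.4
    smooth: float = 1e-5

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth shape {truth.shape}")
    if pred.ndim < 2:
        raise ValueError("expected (C, ...) class-first arrays")
    return pred, truth


def tanimoto_loss_per_class(pred: np.ndarray, truth: np.ndarray, smooth: float = 1e-5) -> np.ndarray:
    """Smoothed Tanimoto loss per class; arrays are class-first (C, ...)."""
    pred, truth = _check_pair(pred, truth)
    if smooth <= 0:
        raise ValueError("smooth must be > 0")
    axes = tuple(range(1, pred.ndim))
    inter = np.sum(pred * truth, axis=axes)
    denom = np.sum(pred * pred, axis=axes) + np.sum(truth * truth, axis=axes) - inter
    return 1.0 - (inter + smooth) / (denom + smooth)


def tanimoto_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = 1e-5) -> float:
    """Class-averaged smoothed Tanimoto loss, in [0, 1]."""
    return float(np.mean(tanimoto_loss_per_class(pred, truth, smooth)))


def categorical_crossentropy(
    pred: np.ndarray, truth: np.ndarray, epsilon: float = CE_EPSILON
) -> float:
    """Mean over voxels of -log p(true class), probabilities clamped to [eps, 1]."""
    pred, truth = _check_pair(pred, truth)
    p_true = np.sum(np.clip(pred, epsilon, 1.0) * truth, axis=0)
    # truth is one-hot, so the sum picks the probability of the true class
    p_true = np.clip(p_true, epsilon, 1.0)
    return float(np.mean(-np.log(p_true)))


def combined_loss(pred: np.ndarray, truth: np.ndarray, config: LossConfig = LossConfig()) -> float:
    """alpha * Tanimoto + beta * crossentropy."""
    return config.alpha * tanimoto_loss(pred, truth, config.smooth) + config.beta * categorical_crossentropy(pred, truth)


def combined_loss_grad(
    pred: np.ndarray, truth: np.ndarray, config: LossConfig = LossConfig()
) -> np.ndarray:
    """Analytic gradient of the combined loss w.r.t. the predicted probabilities.

    Used by the training loop (the softmax backward pass then maps it to
    logit space); validated against numerical differentiation in the tests.
    """
    pred, truth = _check_pair(pred, truth)
    C = pred.shape[0]
    axes = tuple(range(1, pred.ndim))
    n_vox = int(np.prod(pred.shape[1:]))
    s = config.smooth
    inter = np.sum(pred * truth, axis=axes)
    sq = np.sum(pred * pred, axis=axes) + np.sum(truth * truth, axis=axes)
    denom = sq - inter + s
    shape = (C,) + (1,) * (pred.ndim - 1)
    i_s = (inter + s).reshape(shape)
    d_s = denom.reshape(shape)
    # d/dp of -(I+s)/(D+s): quotient rule with dI/dp = y, dD/dp = 2p - y
    grad_t = -(truth * d_s - i_s * (2.0 * pred - truth)) / (d_s * d_s) / C
    clamped = np.clip(pred, CE_EPSILON, 1.0)
    grad_ce = np.where((pred >= CE_EPSILON) & (pred <= 1.0), -truth / clamped, 0.0) / n_vox
    return config.alpha * grad_t + config.beta * grad_ce


def dice_score(
    pred_labels: LabelVolume | np.ndarray,
    truth_labels: LabelVolume | np.ndarray,
    class_id: int,
) -> float:
    """Dice overlap of one class between two label volumes.

    Returns 1.0 when the class is absent from both volumes (the 0/0
    convention; :func:`aggregate_dice` callers can flag such volumes).
    """
    a = pred_labels.data if isinstance(pred_labels, LabelVolume) else np.asarray(pred_labels)
    b = truth_labels.data if isinstance(truth_labels, LabelVolume) else np.asarray(truth_labels)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    pa = (a == class_id).astype(np.float64)
    pb = (b == class_id).astype(np.float64)
    denom = pa.sum() + pb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(pa * pb) / denom)


@dataclass
class DiceReport:
    """Per-class and total Dice, aggregated two ways.

    ``two_level`` averages within folds first, then across folds (the
    headline numbers); ``pooled`` averages over all volumes at once.  The
    raw per-volume table is retained for downstream analysis.
    """

    two_level: pd.DataFrame
    pooled: pd.DataFrame
    raw: pd.DataFrame

    def to_json_summary(self) -> dict:
        return {
            "two_level": self.two_level.reset_index().to_dict(orient="records"),
            "pooled": self.pooled.reset_index().to_dict(orient="records"),
        }


def aggregate_dice(scores: pd.DataFrame) -> DiceReport:
    """Aggregate a long table of (fold, volume, class, score) rows.

    Produces per-class rows plus a "total" row (the unweighted mean of the
    per-class scores within each volume).  Both a two-level (volume-in-fold,
    then fold) and a pooled-over-volumes aggregation are computed since
    "averaged over volumes and folds" admits either reading.
    """
    required = {"fold", "volume", "class", "score"}
    if scores is None or len(scores) == 0:
        raise ValueError("empty score table")
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns {sorted(missing)}")
    raw = scores.copy()
    totals = (
        raw.groupby(["fold", "volume"], sort=True)["score"]
        .mean()
        .reset_index()
        .assign(**{"class": "total"})
    )
    full = pd.concat([raw.assign(**{"class": raw["class"].astype(str)}), totals], ignore_index=True)

    per_fold = full.groupby(["class", "fold"], sort=True)["score"].mean()
    two_level = per_fold.groupby("class").agg(mean="mean", std=lambda s: s.std(ddof=0))
    pooled = full.groupby("class")["score"].agg(mean="mean", std=lambda s: s.std(ddof=0))
    return DiceReport(two_level=two_level, pooled=pd.DataFrame(pooled), raw=raw)
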