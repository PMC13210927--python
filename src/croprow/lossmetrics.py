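"""Combined Focal + Dice training loss and confusion-matrix evaluation suite.

The training objective is ``L_total = L_focal + L_dice`` (unweighted sum):

* Focal loss: mean over pixels of ``-alpha_t * (1 - p_t)^gamma * log(p_t)``,
  where ``p_t`` is the predicted probability of the pixel's true class and
  ``alpha_t`` is ``alpha`` for foreground pixels, ``1 - alpha`` for background.
  With ``gamma = 0`` and ``alpha = 0.5`` it reduces to half the mean binary
  cross-entropy.
* Dice loss (soft formulation on foreground probabilities):
  ``1 - (2 * sum(p*t) + eps) / (sum(p) + sum(t) + eps)``.

Evaluation uses hard (argmax) masks and the binary confusion matrix
TP/FP/FN/TN, from which IoU, mIoU, precision, recall, mPA, f1, the Dice
coefficient and overall accuracy are derived.  For binary masks the Dice
coefficient equals f1.  Degenerate 0/0 ratios are defined as 1 when the class
is absent from both prediction and truth (and flagged), else 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

_P_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Focal/Dice hyper-parameters.

    gamma: focusing exponent (>= 0) down-weighting easy pixels.
    alpha: class-balance weight of the foreground class, in (0, 1).
    eps:   Dice smoothing term preventing 0/0 on empty masks.
    """

    gamma: float = 2.0
    alpha: float = 0.25
    eps: float = 1e-6

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


def _check_probabilities(probs: Tensor) -> None:
    d = probs.data
    if d.ndim != 4 or d.shape[1] != 2:
        raise ValueError("expected probabilities of shape (B, 2, H, W)")
    if np.any(d < -_P_CLAMP) or np.any(d > 1 + _P_CLAMP):
        raise ValueError("probabilities outside [0, 1] beyond clamping tolerance")


def focal_loss(probabilities, targets, config: LossConfig = LossConfig()) -> Tensor:
    """Mean focal loss over all pixels.

    probabilities: Tensor/array (B, 2, H, W), channel 1 = foreground, rows
    normalised over classes; targets: binary array (B, H, W) or (H, W).
    """
    probs = nn.as_tensor(probabilities)
    _check_probabilities(probs)
    t = np.asarray(targets, dtype=probs.data.dtype)
    if t.ndim == 2:
        t = t[None]
    t4 = t[:, None]  # (B,1,H,W)
    # p_t = p1*t + p0*(1-t); alpha_t = alpha*t + (1-alpha)*(1-t)
    sel_fg = np.concatenate([np.zeros_like(t4), np.ones_like(t4)], axis=1)
    sel_bg = 1.0 - sel_fg
    p_true = nn.tsum(nn.mul(probs, sel_fg * t4 + sel_bg * (1.0 - t4)),
                     axis=1, keepdims=False)
    p_true = nn.clip(p_true, _P_CLAMP, 1.0)
    alpha_t = config.alpha * t + (1.0 - config.alpha) * (1.0 - t)
    focal_w = nn.power(1.0 - p_true, config.gamma) if config.gamma != 0 else None
    term = nn.mul(nn.log(p_true), -1.0)
    if focal_w is not None:
        term = nn.mul(term, focal_w)
    term = nn.mul(term, alpha_t)
    return nn.tmean(term)


def dice_loss(probabilities, targets, config: LossConfig = LossConfig()) -> Tensor:
    """Soft Dice loss on foreground probabilities."""
    probs = nn.as_tensor(probabilities)
    _check_probabilities(probs)
    t = np.asarray(targets, dtype=probs.data.dtype)
    if t.ndim == 2:
        t = t[None]
    sel = np.zeros(probs.shape, dtype=probs.data.dtype)
    sel[:, 1] = 1.0
    p_fg = nn.tsum(nn.mul(probs, sel), axis=1, keepdims=False)  # (B,H,W)
    inter = nn.tsum(nn.mul(p_fg, t))
    denom = nn.add(nn.tsum(p_fg), float(t.sum()))
    num = nn.add(nn.mul(inter, 2.0), config.eps)
    return nn.add(1.0, nn.mul(nn.div(num, nn.add(denom, config.eps)), -1.0))


def total_loss(probabilities, targets, config: LossConfig = LossConfig()) -> Tensor:
    """Unweighted sum of focal and Dice losses."""
    probs = nn.as_tensor(probabilities)
    return nn.add(focal_loss(probs, targets, config),
                  dice_loss(probs, targets, config))


# ---------------------------------------------------------------------------
# Confusion matrix and derived metrics (evaluation; plain numpy)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Pixel counts of the four binary-classification quadrants."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be >= 0")


@dataclass(frozen=True)
class SegMetrics:
    """Per-class and averaged segmentation quality measures, all in [0, 1]."""

    iou: tuple[float, float]        # (background, foreground)
    miou: float
    precision: float                # foreground
    recall: float                   # foreground
    mpa: float
    f1: float
    dice: float
    overall_accuracy: float
    degenerate: bool = field(default=False)  # any 0/0 ratio encountered


def confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionMatrix:
    """Exact pixel counts per quadrant for binary masks of equal shape."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        # class absent from both prediction and truth -> perfect by convention
        return 1.0, True
    return num / den, False


def metrics_from_confusion(cm: ConfusionMatrix, n_classes: int = 2) -> SegMetrics:
    """All confusion-derived measures, averaging over the two classes.

    The background class is treated symmetrically, with TN playing the role
    of its TP (and FN/FP swapping).
    """
    if n_classes != 2:
        raise ValueError("only the binary (2-class) setting is supported")
    deg = False
    iou_fg, d1 = _ratio(cm.tp, cm.tp + cm.fp + cm.fn)
    iou_bg, d2 = _ratio(cm.tn, cm.tn + cm.fn + cm.fp)
    precision, d3 = _ratio(cm.tp, cm.tp + cm.fp)
    recall, d4 = _ratio(cm.tp, cm.tp + cm.fn)
    pa_fg, d5 = _ratio(cm.tp, cm.tp + cm.fn)
    pa_bg, d6 = _ratio(cm.tn, cm.tn + cm.fp)
    f1, d7 = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn)
    oa, d8 = _ratio(cm.tp + cm.tn, cm.total)
    deg = any((d1, d2, d3, d4, d5, d6, d7, d8))
    return SegMetrics(
        iou=(iou_bg, iou_fg),
        miou=(iou_bg + iou_fg) / 2.0,
        precision=precision,
        recall=recall,
        mpa=(pa_fg + pa_bg) / 2.0,
        f1=f1,
        dice=f1,  # identical for binary hard masks
        overall_accuracy=oa,
        degenerate=deg,
    )


def evaluate_masks(pred_mask: np.ndarray, true_mask: np.ndarray) -> SegMetrics:
    """Convenience: confusion + metrics in one call."""
    return metrics_from_confusion(confusion(pred_mask, true_mask))
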