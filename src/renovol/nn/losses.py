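"""Combined segmentation loss: soft dice plus categorical cross-entropy.

The dice term for one class is ``1 - 2*sum(t*p) / (sum(t^2) + sum(p^2) + eps)``
with soft probabilities in the numerator and a smoothing constant
``eps = 1e-5`` in the denominator. For multi-class predictions it is the
one-vs-rest dice averaged over foreground classes that are non-empty in the
target (a correctly-empty channel contributes nothing; without this rule a
perfect prediction of a phase with an unused channel could never reach zero
loss). The cross-entropy term is the mean per-voxel negative log
probability of the true class, with probabilities floored at 1e-7. The
combined loss is their unweighted sum — the two terms live on the same
scale, so no weighting is needed.

Array versions (`dice_loss`, `cross_entropy_loss`, `combined_loss`) are the
reference implementations used for evaluation; `combined_loss_from_logits`
builds the same quantity from autograd tensors for training.
"""
from __future__ import annotations

import numpy as np

from .autograd import Tensor, softmax

__all__ = [
    "dice_loss",
    "cross_entropy_loss",
    "combined_loss",
    "one_hot",
    "combined_loss_from_logits",
    "DICE_EPS",
    "PROB_FLOOR",
]

DICE_EPS = 1e-5
PROB_FLOOR = 1e-7


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(D, H, W) integer labels -> (C, D, H, W) one-hot float array."""
    out = np.zeros((n_classes, *labels.shape), dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def _check_shapes(pred, target):
    if np.shape(pred) != np.shape(target):
        raise ValueError(f"shape mismatch: pred {np.shape(pred)} vs target {np.shape(target)}")


def _binary_dice(p, t, eps):
    num = 2.0 * float((t * p).sum())
    den = float((t * t).sum() + (p * p).sum()) + eps
    return 1.0 - num / den


def dice_loss(pred_prob, target, eps: float = DICE_EPS) -> float:
    """Soft dice loss.

    Accepts either binary grids (pred and target of the same shape, target
    in {0, 1}) or multi-class one-hot stacks ``(C, ...)`` where channel 0 is
    background; multi-class input returns the mean one-vs-rest dice over
    foreground channels with a non-empty target (0 if none).
    """
    pred_prob = np.asarray(pred_prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred_prob, target)
    if pred_prob.ndim == 3:
        return _binary_dice(pred_prob, target, eps)
    terms = [
        _binary_dice(pred_prob[c], target[c], eps)
        for c in range(1, pred_prob.shape[0])
        if target[c].sum() > 0
    ]
    return float(np.mean(terms)) if terms else 0.0


def cross_entropy_loss(s_pred, pixel_true, floor: float = PROB_FLOOR) -> float:
    """Mean per-voxel negative log likelihood of the true class.

    ``s_pred`` are probabilities (binary grid or ``(C, ...)`` softmax
    stack); ``pixel_true`` is the matching indicator grid / one-hot stack.
    """
    s_pred = np.clip(np.asarray(s_pred, dtype=np.float64), floor, 1.0)
    pixel_true = np.asarray(pixel_true, dtype=np.float64)
    _check_shapes(s_pred, pixel_true)
    if s_pred.ndim == 3:
        # binary: true voxels score log p, background voxels log (1-p)
        p = np.where(pixel_true > 0.5, s_pred, np.clip(1.0 - s_pred, floor, 1.0))
        return float(-np.log(p).mean())
    n_vox = pixel_true[0].size
    return float(-(pixel_true * np.log(s_pred)).sum() / n_vox)


def combined_loss(pred_prob, target, eps: float = DICE_EPS, floor: float = PROB_FLOOR) -> float:
    """Unweighted sum of the dice and cross-entropy terms."""
    return dice_loss(pred_prob, target, eps) + cross_entropy_loss(pred_prob, target, floor)


def combined_loss_from_logits(logits: Tensor, target_onehot: np.ndarray,
                              eps: float = DICE_EPS, floor: float = PROB_FLOOR) -> Tensor:
    """Autograd version for training: softmax over channel 0, then dice + CE."""
    if tuple(logits.shape) != tuple(target_onehot.shape):
        raise ValueError("shape mismatch between logits and one-hot target")
    p = softmax(logits.reshape(logits.shape[0], -1), axis=0)
    t = target_onehot.reshape(target_onehot.shape[0], -1).astype(logits.data.dtype)
    n_vox = t.shape[1]

    fg = [c for c in range(1, t.shape[0]) if t[c].sum() > 0]
    dice_terms = []
    for c in fg:
        pc = p[c]
        tc = Tensor(t[c])
        num = (pc * tc).sum() * 2.0
        den = (pc * pc).sum() + float((t[c] * t[c]).sum()) + eps
        dice_terms.append(1.0 - num / den)
    dice = sum(dice_terms) * (1.0 / len(dice_terms)) if dice_terms else Tensor(0.0)

    ce = -(Tensor(t) * p.clip_min(floor).log()).sum() * (1.0 / n_vox)
    return dice + ce
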