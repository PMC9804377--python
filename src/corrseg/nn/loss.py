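"""Masked dice + cross-entropy loss for partially annotated images.

Annotations label each pixel foreground, background, or undefined.  Only the
annotated (non-undefined) pixels enter the loss: the cross-entropy term is
the mean two-class negative log-likelihood over them, and the dice term is
``1 - soft-dice`` of the foreground probability against the foreground
labels, restricted to annotated pixels and smoothed with epsilon = 1.  The
two terms are summed unweighted.  Both the value and the analytic gradient
are exactly invariant to the logits at undefined pixels.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

# annotation label codes used throughout the package
UNDEFINED, FOREGROUND, BACKGROUND = 0, 1, 2

DICE_EPS = 1.0


def masked_loss(
    logits: np.ndarray, annotation: np.ndarray, with_grad: bool = True
):
    """Loss (scalar) and d(loss)/d(logits) for a batch.

    Parameters
    ----------
    logits : (N, 2, H, W) array — channel 0 background, channel 1 foreground.
    annotation : (N, H, W) int array of label codes (0/1/2).

    Returns ``(loss, grad)``; grad is ``None`` when ``with_grad`` is false or
    when the batch has no annotated pixels (the batch then contributes 0).
    """
    if logits.shape[0] != annotation.shape[0] or logits.shape[2:] != annotation.shape[1:]:
        raise ValueError("logits and annotation spatial shapes must match")
    mask = annotation != UNDEFINED
    n_ann = int(mask.sum())
    if n_ann == 0:
        return 0.0, (np.zeros_like(logits) if with_grad else None)

    t = (annotation == FOREGROUND).astype(np.float32)
    m = mask.astype(np.float32)
    # two-way softmax reduces to a logistic on the channel difference;
    # p and 1-p are computed separately so neither rounds to exactly 0/1
    # in float32 (which would zero the gradient at saturation)
    d = logits[:, 1] - logits[:, 0]
    p = expit(d)
    q = expit(-d)  # = 1 - p, but accurate in the saturated tails

    # cross-entropy in the numerically stable softplus form:
    # -log p(t) = max(d, 0) - t*d + log(1 + exp(-|d|))
    ce = np.maximum(d, 0.0) - t * d + np.log1p(np.exp(-np.abs(d)))
    ce_loss = float((ce * m).sum() / n_ann)

    # soft dice on the foreground channel over annotated pixels
    inter = float((m * p * t).sum())
    union = float((m * p).sum() + (m * t).sum())
    dice = (2.0 * inter + DICE_EPS) / (union + DICE_EPS)
    loss = ce_loss + (1.0 - dice)

    if not with_grad:
        return loss, None

    # d(ce)/dd = p - t directly; the dice term goes through sigma'(d) = p*q
    dce_dd = (p - t) / n_ann
    ddice_dp = -(2.0 * t * (union + DICE_EPS) - (2.0 * inter + DICE_EPS)) / (
        (union + DICE_EPS) ** 2
    )
    dd = (dce_dd + ddice_dp * p * q) * m
    grad = np.empty_like(logits)
    grad[:, 1] = dd
    grad[:, 0] = -dd
    return loss, grad


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """Pixelwise F1 (dice): 2TP / (2TP + FP + FN); 1.0 when all three are 0."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom
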