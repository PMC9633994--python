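"""Combined soft-Dice + cross-entropy loss for voxelwise K-class segmentation.

For softmax output yhat and one-hot target y over voxel set I and classes K:

    L = -(2/K) * sum_k [ sum_i yhat_i(k) y_i(k) / (sum_i yhat_i(k) + y_i(k)) ]
        + CE(yhat, y)

The Dice term lies in [-1, 0] and reaches -1 exactly at a perfect prediction
with both classes present; the cross-entropy term is non-negative and zero
there. An epsilon guard (1e-5) in the Dice denominator and a floor inside
the log keep degenerate patches (no foreground at all) finite. Cross-entropy
sums over voxels unnormalised by default, as the objective is written; under
extreme class imbalance this keeps a meaningful per-voxel gradient at the
rare foreground voxels. ``ce_reduction="mean"`` instead averages per voxel,
making the Dice/CE balance independent of patch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import softmax_channels

EPS = 1e-5


@dataclass(frozen=True)
class LossTerms:
    dice_term: float
    ce_term: float

    @property
    def total(self) -> float:
        return self.dice_term + self.ce_term


def _check_inputs(softmax_output: np.ndarray, one_hot_target: np.ndarray) -> None:
    if softmax_output.shape != one_hot_target.shape:
        raise ValueError(
            f"shape mismatch: output {softmax_output.shape} vs target {one_hot_target.shape}"
        )
    sums = softmax_output.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("softmax output does not sum to 1 over classes")
    tvals = np.unique(one_hot_target)
    if not np.isin(tvals, (0, 1)).all() or not np.allclose(one_hot_target.sum(axis=0), 1.0):
        raise ValueError("target must be one-hot over the class axis")


def combined_loss(
    softmax_output: np.ndarray,
    one_hot_target: np.ndarray,
    ce_reduction: str = "sum",
    eps: float = EPS,
) -> LossTerms:
    """Evaluate the loss for one patch; arrays are (K, D, H, W)."""
    _check_inputs(softmax_output, one_hot_target)
    k = softmax_output.shape[0]
    yhat = softmax_output.reshape(k, -1).astype(np.float64)
    y = one_hot_target.reshape(k, -1).astype(np.float64)

    num = (yhat * y).sum(axis=1)
    den = (yhat + y).sum(axis=1) + eps
    dice = float(-(2.0 / k) * (num / den).sum())

    ce_per_voxel = -(y * np.log(np.clip(yhat, eps, None))).sum(axis=0)
    if ce_reduction == "mean":
        ce = float(ce_per_voxel.mean())
    elif ce_reduction == "sum":
        ce = float(ce_per_voxel.sum())
    else:
        raise ValueError(f"unknown ce_reduction {ce_reduction!r}")
    return LossTerms(dice_term=dice, ce_term=ce)


def one_hot(label: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """(D, H, W) integer labels -> (K, D, H, W) one-hot float32."""
    out = np.zeros((n_classes,) + label.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = label == c
    return out


def loss_and_grad(
    logits: np.ndarray,
    one_hot_target: np.ndarray,
    ce_reduction: str = "sum",
    eps: float = EPS,
) -> tuple[LossTerms, np.ndarray]:
    """Loss terms and the gradient with respect to the logits, per patch.

    ``logits`` and ``one_hot_target`` are (K, D, H, W). The gradient chains
    the analytic Dice and CE derivatives through the softmax.
    """
    k = logits.shape[0]
    yhat = softmax_channels(logits[None])[0]
    terms = combined_loss(yhat, one_hot_target, ce_reduction=ce_reduction, eps=eps)

    yh = yhat.reshape(k, -1).astype(np.float64)
    y = one_hot_target.reshape(k, -1).astype(np.float64)
    n_vox = yh.shape[1]

    num = (yh * y).sum(axis=1, keepdims=True)
    den = (yh + y).sum(axis=1, keepdims=True) + eps
    # d dice_term / d yhat_i(k) for dice_term = -(2/K) sum_k num_k/den_k
    d_dice = -(2.0 / k) * (y * den - num) / den**2

    d_ce = -(y / np.clip(yh, eps, None))
    if ce_reduction == "mean":
        d_ce = d_ce / n_vox
    elif ce_reduction != "sum":
        raise ValueError(f"unknown ce_reduction {ce_reduction!r}")

    d_yhat = d_dice + d_ce
    # chain through softmax: dz_k = yhat_k * (d_yhat_k - sum_k' d_yhat_k' yhat_k')
    inner = (d_yhat * yh).sum(axis=0, keepdims=True)
    d_logits = yh * (d_yhat - inner)
    return terms, d_logits.reshape(logits.shape).astype(np.float32)
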