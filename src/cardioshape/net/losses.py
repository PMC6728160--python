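"""Training objective of the multi-task network.

The total loss is

    L = L_D + alpha * L_L + beta * ||W||_F^2

where ``L_D`` is the multi-class differentiable Dice loss computed as one
global quotient per sample over all classes and voxels,

    L_D = - sum_i [ 2 * sum_k sum_j 1{r_j=k} p_kj ]
              / [ sum_k sum_j (1{r_j=k}^2 + p_kj^2 + eps) ],

``L_L`` is the class-balanced weighted categorical cross-entropy for the
7-class landmark grid (6 single-voxel landmark classes + background),

    L_L = - sum_k w_k sum_{j in Y_k} log p_kj,   w_k = 1 - |Y_k| / |Y|,

and the Frobenius weight-decay term regularises all convolution kernels.
The balancing weights make the six landmark voxels and the millions of
background voxels contribute at comparable magnitude.

Each loss returns ``(value, gradient-with-respect-to-probabilities)`` so the
network can backpropagate through its softmax heads.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..core import LANDMARK_NAMES, LandmarkSet
from ..errors import GridMismatchError

__all__ = [
    "one_hot",
    "dice_loss",
    "landmark_weights",
    "landmark_loss",
    "total_loss",
    "rasterise_landmarks",
]

LOG_CLAMP = 1e-12  # probability floor inside log to keep the loss finite


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(...)-shaped integer grid -> (n_classes, ...) one-hot float grid."""
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float64)
    for k in range(n_classes):
        out[k][labels == k] = 1.0
    return out


def dice_loss(prob: np.ndarray, truth: np.ndarray, eps: float = 1e-5,
              return_grad: bool = False, per_class: bool = False):
    """Differentiable Dice loss for one sample.

    Parameters
    ----------
    prob : (n_classes, ...) softmax probabilities.
    truth : integer label grid matching ``prob.shape[1:]``.
    eps : smoothing constant added inside the per-(class, voxel) denominator.
    per_class : average per-class quotients instead of the single global
        quotient (a common variant, off by default).

    Returns the scalar loss in ``(-1, 0]`` (or ``(value, d/dprob)``).
    """
    if prob.shape[1:] != truth.shape:
        raise GridMismatchError(
            f"probability grid {prob.shape[1:]} does not match truth {truth.shape}")
    t = one_hot(truth, prob.shape[0])
    if per_class:
        num = 2.0 * (t * prob).reshape(prob.shape[0], -1).sum(axis=1)
        den = (t * t + prob * prob + eps).reshape(prob.shape[0], -1).sum(axis=1)
        value = -float(np.mean(num / den))
        if not return_grad:
            return value
        K = prob.shape[0]
        grad = -(2.0 * t * den.reshape((-1,) + (1,) * truth.ndim)
                 - num.reshape((-1,) + (1,) * truth.ndim) * 2.0 * prob) \
            / (den.reshape((-1,) + (1,) * truth.ndim) ** 2) / K
        return value, grad
    num = 2.0 * float((t * prob).sum())
    den = float((t * t + prob * prob + eps).sum())
    value = -num / den
    if not return_grad:
        return value
    grad = -(2.0 * t * den - num * 2.0 * prob) / (den * den)
    return value, grad


def landmark_weights(lm_labels: np.ndarray, n_classes: int = 7) -> np.ndarray:
    """Class-balancing weights ``w_k = 1 - |Y_k| / |Y|`` on the landmark grid."""
    total = lm_labels.size
    counts = np.bincount(lm_labels.ravel(), minlength=n_classes).astype(np.float64)
    return 1.0 - counts / total


def landmark_loss(prob: np.ndarray, lm_labels: np.ndarray,
                  return_grad: bool = False):
    """Class-balanced weighted categorical cross-entropy for one sample.

    ``prob`` is (n_lm_classes, ...) and ``lm_labels`` an integer grid with 0
    background and classes 1..6 at the landmark voxels.  Probabilities are
    clamped at ``LOG_CLAMP`` inside the log so the loss is always finite.
    """
    if prob.shape[1:] != lm_labels.shape:
        raise GridMismatchError(
            f"probability grid {prob.shape[1:]} does not match truth {lm_labels.shape}")
    n_classes = prob.shape[0]
    w = landmark_weights(lm_labels, n_classes)
    p = np.maximum(prob, LOG_CLAMP)
    value = 0.0
    grad = np.zeros_like(prob) if return_grad else None
    for k in range(n_classes):
        sel = lm_labels == k
        if not sel.any():
            continue
        value -= w[k] * float(np.log(p[k][sel]).sum())
        if return_grad:
            grad[k][sel] = -w[k] / p[k][sel]
    return (value, grad) if return_grad else value


def total_loss(seg_loss: float, lm_loss: float, weights_sqnorm: float,
               alpha: float = 1.0, beta: float = 1e-4) -> float:
    """Combined objective ``L_D + alpha * L_L + beta * ||W||_F^2``."""
    return seg_loss + alpha * lm_loss + beta * weights_sqnorm


def rasterise_landmarks(lm: LandmarkSet, shape: tuple[int, int, int],
                        dilation: int = 0) -> np.ndarray:
    """Paint landmarks onto an integer grid: background 0, classes 1..6 in
    the canonical landmark order, one voxel each (optionally dilated by a
    ball of ``dilation`` voxels to give the localisation task more support).
    """
    grid = np.zeros(shape, dtype=np.int16)
    for idx, name in enumerate(LANDMARK_NAMES, start=1):
        if name not in lm.voxel:
            continue
        i, j, k = (int(np.clip(c, 0, s - 1)) for c, s in zip(lm.voxel[name], shape))
        grid[i, j, k] = idx
    if dilation > 0:
        struct = ndimage.generate_binary_structure(3, 3)
        for idx in range(1, 7):
            mask = ndimage.binary_dilation(grid == idx, structure=struct,
                                           iterations=dilation)
            grid[mask & (grid == 0)] = idx
    return grid
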