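"""Weighted cross-entropy loss and its gradients.

The training criterion is, per sample,

    Loss = -sum_i  w_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]

over the c classes, where ``w_i`` is the class weight, ``y_i`` the desired
(one-hot) output and ``p_i`` the predicted probability.  With all weights 1
this is the per-class binary cross-entropy sum.  Probabilities are clipped at
1e-7 away from {0, 1} before taking logarithms.
"""

from __future__ import annotations

import numpy as np

CLIP = 1e-7


def weighted_ce_loss(p, y, w) -> float:
    """Loss for a single probability vector (or a batch; batches are averaged).

    Parameters
    ----------
    p : array, shape (c,) or (n, c)
        Predicted class probabilities; each row must sum to 1 within 1e-6.
    y : array, same shape
        Desired output (one-hot rows).
    w : array, shape (c,)
        Positive class weights.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    w = np.asarray(w, dtype=float)
    if p.shape != y.shape or p.shape[1] != w.size:
        raise ValueError("p, y and w shapes are inconsistent")
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("each probability row must sum to 1")
    pc = np.clip(p, CLIP, 1.0 - CLIP)
    per_sample = -(w[None, :] * (y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))).sum(axis=1)
    return float(per_sample.mean())


def softmax(z: np.ndarray) -> np.ndarray:
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=1, keepdims=True)


def softmax_weighted_ce(z: np.ndarray, y_onehot: np.ndarray, w: np.ndarray):
    """Loss and gradient w.r.t. logits for a softmax output.

    Returns ``(loss, dz)`` where the loss is averaged over the batch.
    """
    p = softmax(z)
    pc = np.clip(p, CLIP, 1.0 - CLIP)
    n = z.shape[0]
    loss = float(-(w[None, :] * (y_onehot * np.log(pc)
                                 + (1 - y_onehot) * np.log(1 - pc))).sum() / n)
    g = -(w[None, :] * (y_onehot / pc - (1 - y_onehot) / (1 - pc))) / n
    dz = p * (g - (g * p).sum(axis=1, keepdims=True))
    return loss, dz


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_weighted_ce(z: np.ndarray, y: np.ndarray, w_neg: float, w_pos: float):
    """Binary weighted cross-entropy on a single logit per sample.

    Returns ``(loss, dz)``; ``y`` holds 0/1 targets.
    """
    p = sigmoid(z)
    pc = np.clip(p, CLIP, 1.0 - CLIP)
    n = z.shape[0]
    loss = float(-(w_pos * y * np.log(pc) + w_neg * (1 - y) * np.log(1 - pc)).sum() / n)
    dz = (-w_pos * y * (1 - p) + w_neg * (1 - y) * p) / n
    return loss, dz
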