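"""Pixel-wise losses on probability maps, each returning (value, gradient).

Both losses operate on softmax outputs rather than logits; gradients are
meant to be fed back through a :class:`~lccnet.nn.layers.Softmax2d`.
"""

from __future__ import annotations

import numpy as np

PROB_CLAMP = 1e-7


def cross_entropy_from_probs(probs: np.ndarray, labels: np.ndarray):
    """Mean multiclass cross-entropy of probability maps against integer labels.

    Parameters
    ----------
    probs : (N, K, H, W) probability maps
    labels : (N, H, W) integer class maps in {0..K-1}

    Returns
    -------
    loss : float
        mean over samples and pixels of ``-log p[label]`` (probabilities are
        clamped at ``1e-7`` before the log)
    dprobs : (N, K, H, W) gradient of the loss w.r.t. ``probs``
    """
    N, K, H, W = probs.shape
    labels = np.asarray(labels)
    if labels.shape != (N, H, W):
        raise ValueError(f"labels shape {labels.shape} does not match probs {probs.shape}")
    if labels.min() < 0 or labels.max() >= K:
        raise ValueError(f"label values must lie in 0..{K - 1}")
    idx_n, idx_h, idx_w = np.ogrid[:N, :H, :W]
    p_true = probs[idx_n, labels, idx_h, idx_w]
    p_clamped = np.maximum(p_true, PROB_CLAMP)
    loss = float(-np.log(p_clamped).mean())
    dprobs = np.zeros_like(probs)
    scale = -1.0 / (N * H * W)
    grad_vals = np.where(p_true > PROB_CLAMP, scale / p_clamped, 0.0).astype(probs.dtype)
    dprobs[idx_n, labels, idx_h, idx_w] = grad_vals
    return loss, dprobs


def mse_consistency(p_pred: np.ndarray, p_target: np.ndarray):
    """Mean squared error between two probability maps.

    ``p_target`` is treated as a constant (stop-gradient): only the gradient
    w.r.t. ``p_pred`` is returned.
    """
    if p_pred.shape != p_target.shape:
        raise ValueError(f"shape mismatch: {p_pred.shape} vs {p_target.shape}")
    diff = p_pred - p_target
    loss = float(np.mean(diff * diff))
    dpred = (2.0 / diff.size) * diff
    return loss, dpred.astype(p_pred.dtype)
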