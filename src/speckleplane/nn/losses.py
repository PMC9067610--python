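"""Training losses with analytic gradients.

The reconstruction loss is the negative Pearson correlation coefficient
(NPCC) between each predicted image and its ground truth, averaged over the
batch.  With centered vectors xc = x - mean(x), yc = y - mean(y) and
r = <xc, yc> / (|xc| |yc|), the loss per pair is -r and

    d(-r)/dy = -(xc / (|xc| |yc|) - r * yc / |yc|^2) projected off the mean,

the projection accounting for the centering of y.
"""

from __future__ import annotations

import numpy as np


def npcc_loss_and_grad(pred: np.ndarray, target: np.ndarray, eps: float = 1e-8):
    """Mean per-image NPCC over a batch, plus the gradient w.r.t. ``pred``.

    ``pred`` and ``target`` are (N, 1, H, W) or (N, H, W).  Returns
    (loss, grad) with grad shaped like pred.
    """
    p = pred.reshape(pred.shape[0], -1).astype(np.float64)
    t = target.reshape(target.shape[0], -1).astype(np.float64)
    if p.shape != t.shape:
        raise ValueError("prediction/target shape mismatch")
    n_img = p.shape[0]
    pc = p - p.mean(axis=1, keepdims=True)
    tc = t - t.mean(axis=1, keepdims=True)
    np_norm = np.sqrt((pc**2).sum(axis=1)) + eps
    nt_norm = np.sqrt((tc**2).sum(axis=1)) + eps
    cov = (pc * tc).sum(axis=1)
    r = cov / (np_norm * nt_norm)
    loss = float(-r.mean())
    # d(-r)/dpc, then subtract its mean (adjoint of centering), then / n_img
    g = -(tc / (np_norm * nt_norm)[:, None] - (r / np_norm**2)[:, None] * pc)
    g -= g.mean(axis=1, keepdims=True)
    g /= n_img
    return loss, g.reshape(pred.shape).astype(pred.dtype)


def softmax_xent_and_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch of (N, K) logits with int labels."""
    z = logits.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    prob = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = float(-np.log(prob[np.arange(n), labels] + 1e-300).mean())
    grad = prob
    grad[np.arange(n), labels] -= 1.0
    grad /= n
    return loss, grad.astype(logits.dtype)
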