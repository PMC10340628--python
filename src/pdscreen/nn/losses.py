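"""Softmax and cross-entropy with analytic gradients."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over a batch of integer labels.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss w.r.t. the logits (already divided by the batch size).
    """
    B = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(B), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    return float(loss), dlogits / B
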