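"""Loss primitives. Gradients are with respect to the *mean* loss, so layer
backward passes need no extra batch normalization factor."""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    Returns (loss, dlogits); dlogits already carries the 1/N factor.
    """
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.mean(np.log(np.clip(p[np.arange(n), labels], EPS, None)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def bce(p, t):
    """Binary cross-entropy, mean over all elements; supports soft targets in [0,1]."""
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def bce_grad(p, t):
    """d(mean BCE)/dp."""
    p = np.clip(p, EPS, 1.0 - EPS)
    return (p - t) / (p * (1.0 - p)) / p.size


def mae(a, b):
    return float(np.mean(np.abs(a - b)))


def mae_grad(a, b):
    """d(mean |a-b|)/da."""
    return np.sign(a - b) / a.size
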