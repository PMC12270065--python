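"""Losses returning (scalar value, gradient with respect to the first input)."""

from __future__ import annotations

import numpy as np


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error."""
    d = pred - target
    grad = np.sign(d) / d.size
    return float(np.abs(d).mean()), grad


def weighted_l1_loss(pred: np.ndarray, target: np.ndarray, weights: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    """Sum w|pred - target| / sum w, weights broadcast against the error."""
    weights = np.broadcast_to(np.asarray(weights, dtype=float), pred.shape)
    wsum = weights.sum()
    if wsum == 0:
        raise ValueError("all loss weights are zero")
    d = pred - target
    value = float((weights * np.abs(d)).sum() / wsum)
    grad = weights * np.sign(d) / wsum
    return value, grad


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def bce_with_logits(logits: np.ndarray, label: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits against a constant label (0 or 1).

    BCE(z, y) = softplus(z) - y*z, averaged; gradient sigmoid(z) - y, /n.
    """
    z = np.asarray(logits, dtype=float)
    value = float((_softplus(z) - label * z).mean())
    sig = 1.0 / (1.0 + np.exp(-z))
    return value, (sig - label) / z.size
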