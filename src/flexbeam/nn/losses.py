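"""Losses for the adversarial delay-prediction network.

Both return ``(value, grad_wrt_first_argument)``; gradients are of the mean
loss, matching the optimizer's expectation of already-averaged gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bce_loss", "l1_loss"]

_EPS = 1e-12


def bce_loss(p: np.ndarray, target: float | np.ndarray):
    """Binary cross-entropy of probabilities ``p`` against labels.

    ``target`` may be a scalar label (broadcast) or an array.  The returned
    gradient is with respect to ``p`` itself; backpropagating it through the
    producing sigmoid is numerically stable.
    """
    p = np.asarray(p)
    t = np.broadcast_to(np.asarray(target, dtype=float), p.shape)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    value = float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
    grad = (pc - t) / (pc * (1.0 - pc)) / p.size
    return value, grad


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its (sub)gradient with respect to ``pred``."""
    diff = np.asarray(pred) - np.asarray(target)
    value = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return value, grad
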