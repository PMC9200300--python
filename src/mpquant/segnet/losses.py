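"""Segmentation losses with analytic gradients w.r.t. the logits.

* soft Dice: ``1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s)`` with
  smoothing ``s = 1``, aggregated over the whole batch;
* BCE-with-logits in the numerically stable form
  ``max(z, 0) - z*t + log(1 + exp(-|z|))``, averaged over pixels;
* Dice+BCE: their unweighted sum.

Each ``*_grad`` companion returns (loss, dL/dlogits) so the training loop
never differentiates through the sigmoid twice.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "dice_loss",
    "bce_logits_loss",
    "dice_bce_loss",
    "loss_and_grad",
]

DICE_SMOOTH = 1.0


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_loss(prob: np.ndarray, target: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice loss on probabilities; in [0, 1]."""
    _check(prob, target)
    p = np.asarray(prob, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + smooth) / (denom + smooth)


def _dice_grad_wrt_prob(p: np.ndarray, t: np.ndarray, smooth: float) -> np.ndarray:
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + smooth
    return -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2


def bce_logits_loss(logits: np.ndarray, target: np.ndarray) -> float:
    """Mean binary cross-entropy computed stably from logits."""
    _check(logits, target)
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    per = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    return float(per.mean())


def dice_bce_loss(logits: np.ndarray, target: np.ndarray) -> float:
    """Unweighted sum of soft Dice (on sigmoid(logits)) and BCE."""
    return dice_loss(sigmoid(logits), target) + bce_logits_loss(logits, target)


def loss_and_grad(
    name: str, logits: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """Evaluate the named loss and its gradient w.r.t. the logits."""
    _check(logits, target)
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    p = sigmoid(z)
    dsig = p * (1.0 - p)

    if name == "dice":
        loss = dice_loss(p, t)
        grad = _dice_grad_wrt_prob(p, t, DICE_SMOOTH) * dsig
    elif name == "bce_logits":
        loss = bce_logits_loss(z, t)
        grad = (p - t) / z.size
    elif name == "dice_bce":
        loss = dice_loss(p, t) + bce_logits_loss(z, t)
        grad = _dice_grad_wrt_prob(p, t, DICE_SMOOTH) * dsig + (p - t) / z.size
    else:
        raise ValueError(f"unknown loss {name!r}")
    return float(loss), grad.astype(np.float32)
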