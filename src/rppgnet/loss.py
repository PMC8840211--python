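"""Negative Pearson correlation loss for waveform regression.

Training an rPPG network against a reference pulse waveform cares about trend
and peak timing, not absolute scale or offset, so the loss is 1 - r where r is
the sample Pearson correlation between the predicted and reference traces:
0 for perfect correlation, 2 for perfect anti-correlation, invariant to
positive affine rescaling of either trace.

Two surfaces are provided: strict analysis-mode functions on numpy arrays
(which reject zero-variance inputs) and an autograd-aware ``neg_pearson_loss``
for training, which regularizes the denominator with a small epsilon so a
momentarily flat prediction does not crash a run.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor

__all__ = [
    "pearson_r",
    "neg_pearson",
    "neg_pearson_loss",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """A series has zero variance, so its correlation is undefined."""


def _validate_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least two samples")
    return x, y


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient in [-1, 1]."""
    x, y = _validate_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("constant series: correlation undefined")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def neg_pearson(x, y) -> float:
    """1 - r: 0 iff perfectly correlated, 2 iff perfectly anti-correlated."""
    return 1.0 - pearson_r(x, y)


def neg_pearson_loss(pred: Tensor, target, eps: float = 1e-8) -> Tensor:
    """Differentiable mean negative-Pearson loss over a batch of traces.

    ``pred`` and ``target`` are (B, T) (or (T,), treated as a batch of one).
    The loss is the mean of the per-clip losses, so its scale does not depend
    on the batch size.
    """
    pred = as_tensor(pred)
    target = as_tensor(target, dtype=pred.dtype)
    if pred.ndim == 1:
        pred = pred.reshape(1, -1)
        target = target.reshape(1, -1)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    B, T = pred.shape
    if T < 2:
        raise ValueError("need at least two samples per clip")
    xc = pred - pred.mean(axis=1, keepdims=True)
    yc = target - target.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = (((xc * xc).sum(axis=1) + eps) * ((yc * yc).sum(axis=1) + eps)) ** 0.5
    r = num / den
    return (1.0 - r).mean()
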