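"""Huber loss for multi-task regression on standardized targets.

The Huber loss blends the squared error's sensitivity near zero with the
absolute error's robustness to outliers: quadratic within ±delta of a zero
residual, linear beyond, continuous and once-differentiable at the joint.
Maize phenotypes contain genuine extreme plots, so a pure squared error
would let a few outliers dominate the fit while a pure absolute error would
under-weight ordinary residuals.
"""

from __future__ import annotations

import numpy as np


def huber_loss(y, f, delta: float = 1.0):
    """Elementwise Huber loss: ½r² for |r| ≤ δ, δ|r| − ½δ² beyond (r = y − f)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(y, dtype=float) - np.asarray(f, dtype=float)
    a = np.abs(r)
    out = np.where(a <= delta, 0.5 * r * r, delta * a - 0.5 * delta * delta)
    return float(out) if out.ndim == 0 else out


def huber_grad_wrt_prediction(y: np.ndarray, f: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """dL/df, elementwise: −r clipped to ±δ."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.asarray(y, dtype=float) - np.asarray(f, dtype=float)
    return -np.clip(r, -delta, delta)


def multitask_huber(y: np.ndarray, f: np.ndarray, delta: float = 1.0) -> tuple[float, np.ndarray]:
    """Unweighted mean Huber loss over tasks and samples, plus dL/df.

    Targets are assumed standardized per task, which makes an unweighted
    mean across tasks a comparable aggregate.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    f = np.atleast_2d(np.asarray(f, dtype=float))
    loss = float(np.mean(huber_loss(y, f, delta)))
    grad = huber_grad_wrt_prediction(y, f, delta) / y.size
    return loss, grad
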