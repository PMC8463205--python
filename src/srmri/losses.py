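"""Training losses and their gradients with respect to the predictions.

Three candidate objectives are provided for the reconstruction network:

* ``"mse"`` — mean square error, ``sum_i (y_i - yhat_i)^2 / m``. The
  default training loss: pixel-wise, convex in the predictions, and the
  one that trains fastest in practice for this architecture.
* ``"cross_entropy"`` — the binary cross-entropy
  ``-(1/m) sum_i [y_i log h_i + (1 - y_i) log(1 - h_i)]``. Note the
  leading minus sign: the quantity returned here is the conventional
  non-negative cross-entropy, minimized when ``h = y``, so that
  "minimize the loss" is well-posed for all three options.
* ``"log_likelihood"`` — the negative log-likelihood
  ``-sum_i y_i ln h_i``, non-negative for targets in [0, 1].

For image training the pixel intensities in [0, 1] are treated as
Bernoulli targets, and predictions entering the two logarithmic losses
are clamped to ``[eps, 1 - eps]`` with ``eps = 1e-7``; the gradient is
zero where the clamp is active.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError

__all__ = [
    "LOSS_KINDS",
    "CLAMP_EPS",
    "mse_loss",
    "cross_entropy_loss",
    "log_likelihood_loss",
    "loss_value",
    "loss_gradient",
]

LOSS_KINDS = ("mse", "cross_entropy", "log_likelihood")
CLAMP_EPS = 1e-7


def _as_batch(predictions, targets) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=np.float64).ravel()
    t = np.asarray(targets, dtype=np.float64).ravel()
    if p.size == 0:
        raise ConfigurationError("empty batch")
    if p.size != t.size:
        raise ConfigurationError(
            f"predictions ({p.size}) and targets ({t.size}) must have equal length"
        )
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise DegenerateInputError("non-finite values in batch")
    return p, t


def mse_loss(predictions, targets) -> float:
    """Mean square error ``sum (y - yhat)^2 / m``."""
    p, t = _as_batch(predictions, targets)
    return float(np.mean((t - p) ** 2))


def cross_entropy_loss(predictions, targets) -> float:
    """Non-negative binary cross-entropy with clamped predictions."""
    p, t = _as_batch(predictions, targets)
    h = np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return float(-np.mean(t * np.log(h) + (1.0 - t) * np.log(1.0 - h)))


def log_likelihood_loss(predictions, targets) -> float:
    """Negative log-likelihood ``-sum y ln h`` with clamped predictions."""
    p, t = _as_batch(predictions, targets)
    h = np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)
    return float(-np.sum(t * np.log(h)))


_LOSSES = {
    "mse": mse_loss,
    "cross_entropy": cross_entropy_loss,
    "log_likelihood": log_likelihood_loss,
}


def loss_value(predictions, targets, kind: str = "mse") -> float:
    """Evaluate the named loss on a batch."""
    try:
        fn = _LOSSES[kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown loss {kind!r}; expected one of {LOSS_KINDS}"
        ) from None
    return fn(predictions, targets)


def loss_gradient(predictions, targets, kind: str = "mse") -> np.ndarray:
    """Elementwise ``d loss / d prediction`` on the flattened batch.

    For the logarithmic losses the derivative is taken through the clamp:
    entries whose raw prediction lies outside ``(eps, 1 - eps)`` get
    gradient zero.
    """
    p, t = _as_batch(predictions, targets)
    m = p.size
    if kind == "mse":
        return 2.0 * (p - t) / m
    if kind in ("cross_entropy", "log_likelihood"):
        h = np.clip(p, CLAMP_EPS, 1.0 - CLAMP_EPS)
        inside = (p > CLAMP_EPS) & (p < 1.0 - CLAMP_EPS)
        if kind == "cross_entropy":
            g = -(t / h - (1.0 - t) / (1.0 - h)) / m
        else:
            g = -t / h
        return np.where(inside, g, 0.0)
    raise ConfigurationError(f"unknown loss {kind!r}; expected one of {LOSS_KINDS}")
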