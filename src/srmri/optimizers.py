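"""First-order parameter-update rules: SGD, momentum, RMSProp, Adam.

All four rules are applied uniformly to every weight and bias array of
the model. With gradient g and learning rate alpha:

* ``sgd``        w <- w - alpha * g
* ``momentum``   D <- beta*D + (1-beta)*g;            w <- w - alpha*D
* ``rmsprop``    E <- beta*E + (1-beta)*g^2;          w <- w - alpha*g/(sqrt(E)+theta)
* ``adam``       D <- beta1*D + (1-beta1)*g;  E <- beta2*E + (1-beta2)*g^2;
                 Dhat = D/(1-beta1^t);  Ehat = E/(1-beta2^t);
                 w <- w - alpha * Dhat/(sqrt(Ehat)+theta)

Adam's bias correction divides the zero-initialized moment accumulators
by ``1 - beta^t`` so early steps are not shrunk toward zero; ``t`` is a
single global iteration counter per training run. The stability constant
theta sits outside the square root. Defaults: beta1 = 0.9, beta2 = 0.999,
theta = 1e-8, and beta = 0.9 for momentum/RMSProp.

The functional ``step`` never mutates its inputs; it returns fresh
parameter arrays and a fresh state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, ShapeError

__all__ = ["OPTIMIZER_KINDS", "OptimizerConfig", "OptimizerState", "init_state", "step", "reset"]

OPTIMIZER_KINDS = ("sgd", "momentum", "rmsprop", "adam")

_DEFAULT_LR = {"sgd": 1e-2, "momentum": 1e-2, "rmsprop": 1e-3, "adam": 1e-3}


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters of the update rule.

    ``learning_rate=None`` selects a per-kind default (1e-2 for sgd and
    momentum, 1e-3 for rmsprop and adam).
    """

    kind: str = "adam"
    learning_rate: float | None = None
    beta: float = 0.9       # momentum / RMSProp decay
    beta1: float = 0.9      # Adam first-moment decay
    beta2: float = 0.999    # Adam second-moment decay
    theta: float = 1e-8     # stability constant

    def __post_init__(self) -> None:
        if self.kind not in OPTIMIZER_KINDS:
            raise ConfigurationError(
                f"unknown optimizer {self.kind!r}; expected one of {OPTIMIZER_KINDS}"
            )
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        for name in ("beta", "beta1", "beta2"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1), got {v}")
        if self.theta <= 0:
            raise ConfigurationError("theta must be > 0")

    @property
    def alpha(self) -> float:
        return self.learning_rate if self.learning_rate is not None else _DEFAULT_LR[self.kind]


@dataclass
class OptimizerState:
    """Iteration counter plus per-parameter moment accumulators.

    ``first_moments`` holds the momentum/Adam D accumulators and
    ``second_moments`` the RMSProp/Adam E accumulators; both start at
    zero with ``t = 0``.
    """

    t: int
    first_moments: list[np.ndarray]
    second_moments: list[np.ndarray]


def init_state(params: list[np.ndarray]) -> OptimizerState:
    """Zeroed state shaped like the parameter list."""
    return OptimizerState(
        t=0,
        first_moments=[np.zeros_like(p) for p in params],
        second_moments=[np.zeros_like(p) for p in params],
    )


def reset(state: OptimizerState) -> OptimizerState:
    """Return a zeroed state of the same shapes (t = 0, accumulators 0)."""
    return OptimizerState(
        t=0,
        first_moments=[np.zeros_like(m) for m in state.first_moments],
        second_moments=[np.zeros_like(v) for v in state.second_moments],
    )


def step(
    params: list[np.ndarray],
    grads: list[np.ndarray],
    state: OptimizerState,
    config: OptimizerConfig,
) -> tuple[list[np.ndarray], OptimizerState]:
    """Apply one update of the configured rule to every parameter array.

    The counter is incremented first, so the Adam bias correction at the
    first call uses t = 1.
    """
    if len(params) != len(grads) or len(params) != len(state.first_moments):
        raise ShapeError("params, grads and state must have equal lengths")
    for p, g in zip(params, grads):
        if p.shape != g.shape:
            raise ShapeError(f"gradient shape {g.shape} != parameter shape {p.shape}")
    a = config.alpha
    t = state.t + 1
    new_params: list[np.ndarray] = []
    new_m: list[np.ndarray] = []
    new_v: list[np.ndarray] = []
    if config.kind == "sgd":
        for p, g, m, v in zip(params, grads, state.first_moments, state.second_moments):
            new_params.append(p - a * g)
            new_m.append(m.copy())
            new_v.append(v.copy())
    elif config.kind == "momentum":
        b = config.beta
        for p, g, m, v in zip(params, grads, state.first_moments, state.second_moments):
            d = b * m + (1.0 - b) * g
            new_params.append(p - a * d)
            new_m.append(d)
            new_v.append(v.copy())
    elif config.kind == "rmsprop":
        b, th = config.beta, config.theta
        for p, g, m, v in zip(params, grads, state.first_moments, state.second_moments):
            e = b * v + (1.0 - b) * g**2
            new_params.append(p - a * g / (np.sqrt(e) + th))
            new_m.append(m.copy())
            new_v.append(e)
    else:  # adam
        b1, b2, th = config.beta1, config.beta2, config.theta
        c1 = 1.0 - b1**t
        c2 = 1.0 - b2**t
        for p, g, m, v in zip(params, grads, state.first_moments, state.second_moments):
            d = b1 * m + (1.0 - b1) * g
            e = b2 * v + (1.0 - b2) * g**2
            dhat = d / c1
            ehat = e / c2
            new_params.append(p - a * dhat / (np.sqrt(ehat) + th))
            new_m.append(d)
            new_v.append(e)
    return new_params, OptimizerState(t=t, first_moments=new_m, second_moments=new_v)
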