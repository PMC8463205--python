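"""Update rules: SGD, momentum, RMSProp, Adam.

The central check is a standalone scalar re-implementation of all four
rules (plain Python floats, no arrays) that the vectorized step must
match to 1e-12 over long random gradient sequences.
"""

import math

import numpy as np
import pytest

from srmri.exceptions import ConfigurationError, ShapeError
from srmri.optimizers import (
    OPTIMIZER_KINDS,
    OptimizerConfig,
    OptimizerState,
    init_state,
    reset,
    step,
)


def scalar_oracle(kind, grads, w0, alpha, beta=0.9, beta1=0.9, beta2=0.999, theta=1e-8):
    """Pure-Python scalar update rules, written independently of the
    vectorized implementation."""
    w = w0
    d = 0.0
    e = 0.0
    t = 0
    trajectory = []
    for g in grads:
        t += 1
        if kind == "sgd":
            w = w - alpha * g
        elif kind == "momentum":
            d = beta * d + (1 - beta) * g
            w = w - alpha * d
        elif kind == "rmsprop":
            e = beta * e + (1 - beta) * g * g
            w = w - alpha * g / (math.sqrt(e) + theta)
        elif kind == "adam":
            d = beta1 * d + (1 - beta1) * g
            e = beta2 * e + (1 - beta2) * g * g
            dhat = d / (1 - beta1**t)
            ehat = e / (1 - beta2**t)
            w = w - alpha * dhat / (math.sqrt(ehat) + theta)
        trajectory.append(w)
    return trajectory


class TestScalarOracleEquivalence:
    @pytest.mark.parametrize("kind", OPTIMIZER_KINDS)
    def test_vectorized_matches_scalar_over_100_steps(self, rng, kind):
        grads = rng.normal(size=100)
        cfg = OptimizerConfig(kind=kind, learning_rate=0.05)
        params = [np.array([1.0])]
        state = init_state(params)
        expected = scalar_oracle(kind, grads, 1.0, 0.05)
        for g, w_exp in zip(grads, expected):
            params, state = step(params, [np.array([g])], state, cfg)
            assert abs(params[0][0] - w_exp) < 1e-12

    @pytest.mark.parametrize("kind", OPTIMIZER_KINDS)
    def test_elementwise_independence(self, rng, kind):
        """A vector parameter behaves as independent scalars."""
        n = 5
        grad_seq = rng.normal(size=(20, n))
        cfg = OptimizerConfig(kind=kind, learning_rate=0.03)
        params = [np.ones(n)]
        state = init_state(params)
        for g in grad_seq:
            params, state = step(params, [g], state, cfg)
        for i in range(n):
            expected = scalar_oracle(kind, grad_seq[:, i], 1.0, 0.03)[-1]
            assert abs(params[0][i] - expected) < 1e-12


class TestAdam:
    def test_hand_evaluated_first_step(self):
        """w=1, g=1, alpha=0.1, t=1: D=0.1, E=0.001, Dhat=1, Ehat=1,
        w' = 1 - 0.1/(1 + 1e-8)."""
        cfg = OptimizerConfig(kind="adam", learning_rate=0.1)
        params, state = step([np.array([1.0])], [np.array([1.0])], init_state([np.array([1.0])]), cfg)
        assert state.t == 1
        assert state.first_moments[0][0] == pytest.approx(0.1)
        assert state.second_moments[0][0] == pytest.approx(0.001)
        assert params[0][0] == pytest.approx(1.0 - 0.1 / (1.0 + 1e-8), abs=1e-15)

    @pytest.mark.parametrize("gmag", [1e-3, 1.0, 1e3])
    def test_first_step_magnitude_is_learning_rate(self, gmag):
        """Bias correction makes the first Adam step ~alpha regardless of
        gradient magnitude."""
        alpha = 0.01
        cfg = OptimizerConfig(kind="adam", learning_rate=alpha)
        p0 = np.array([0.0])
        params, _ = step([p0], [np.array([gmag])], init_state([p0]), cfg)
        assert abs(params[0][0]) == pytest.approx(alpha, rel=1e-4)


class TestDegenerateEquivalences:
    def test_momentum_beta_zero_is_plain_sgd(self, rng):
        grads = rng.normal(size=(30, 3))
        sgd_cfg = OptimizerConfig(kind="sgd", learning_rate=0.02)
        mom_cfg = OptimizerConfig(kind="momentum", learning_rate=0.02, beta=0.0)
        p_sgd, s_sgd = [np.zeros(3)], init_state([np.zeros(3)])
        p_mom, s_mom = [np.zeros(3)], init_state([np.zeros(3)])
        for g in grads:
            p_sgd, s_sgd = step(p_sgd, [g], s_sgd, sgd_cfg)
            p_mom, s_mom = step(p_mom, [g], s_mom, mom_cfg)
            np.testing.assert_array_equal(p_sgd[0], p_mom[0])

    @pytest.mark.parametrize("kind", OPTIMIZER_KINDS)
    def test_zero_gradient_leaves_parameters_unchanged(self, kind):
        cfg = OptimizerConfig(kind=kind)
        p0 = np.array([2.5, -1.0])
        params, _ = step([p0.copy()], [np.zeros(2)], init_state([p0]), cfg)
        np.testing.assert_array_equal(params[0], p0)

    @pytest.mark.parametrize("kind", OPTIMIZER_KINDS)
    def test_single_step_decreases_quadratic(self, kind):
        """Sign correctness: one small step on f(w) = w^2 from w=1."""
        cfg = OptimizerConfig(kind=kind, learning_rate=1e-3)
        w = np.array([1.0])
        params, _ = step([w], [2.0 * w], init_state([w]), cfg)
        assert params[0][0] ** 2 < 1.0


class TestConvergenceRace:
    def test_adaptive_methods_beat_sgd_on_ill_conditioned_quadratic(self):
        """On f(x, y) = 50 x^2 + 0.5 y^2 with one shared small learning
        rate, RMSProp and Adam reach f < 1e-3 in fewer iterations than
        plain gradient descent."""

        def iterations_to_converge(kind, alpha=0.008, max_iter=20000):
            cfg = OptimizerConfig(kind=kind, learning_rate=alpha)
            params = [np.array([1.0, 1.0])]
            state = init_state(params)
            for i in range(1, max_iter + 1):
                x, y = params[0]
                grad = np.array([100.0 * x, 1.0 * y])
                params, state = step(params, [grad], state, cfg)
                x, y = params[0]
                if 50.0 * x**2 + 0.5 * y**2 < 1e-3:
                    return i
            return max_iter + 1

        n_sgd = iterations_to_converge("sgd")
        n_rms = iterations_to_converge("rmsprop")
        n_adam = iterations_to_converge("adam")
        assert n_rms < n_sgd
        assert n_adam < n_sgd


class TestStateManagement:
    def test_reset_zeroes_everything(self, rng):
        cfg = OptimizerConfig(kind="adam", learning_rate=0.1)
        params = [rng.normal(size=(2, 2))]
        state = init_state(params)
        for _ in range(5):
            params, state = step(params, [rng.normal(size=(2, 2))], state, cfg)
        fresh = reset(state)
        assert fresh.t == 0
        np.testing.assert_array_equal(fresh.first_moments[0], 0.0)
        np.testing.assert_array_equal(fresh.second_moments[0], 0.0)

    def test_reset_idempotent_and_equals_fresh(self):
        params = [np.zeros(3)]
        state = init_state(params)
        r1 = reset(state)
        r2 = reset(r1)
        fresh = init_state(params)
        assert r1.t == r2.t == fresh.t == 0
        np.testing.assert_array_equal(r2.first_moments[0], fresh.first_moments[0])

    def test_step_after_reset_with_zero_gradient_is_noop(self):
        cfg = OptimizerConfig(kind="momentum", learning_rate=0.5)
        params = [np.array([1.0])]
        state = init_state(params)
        params, state = step(params, [np.array([10.0])], state, cfg)
        state = reset(state)
        p_after, _ = step(params, [np.array([0.0])], state, cfg)
        np.testing.assert_array_equal(p_after[0], params[0])

    def test_shape_mismatch_rejected(self):
        cfg = OptimizerConfig(kind="sgd")
        params = [np.zeros(3)]
        with pytest.raises(ShapeError):
            step(params, [np.zeros(4)], init_state(params), cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(kind="adagrad"),
            dict(kind="adam", learning_rate=-0.1),
            dict(kind="adam", beta1=1.0),
            dict(kind="adam", theta=0.0),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(**kwargs)
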