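"""Shared fixtures.

The desk-scale study conditions — 12 phantoms of 48x48 with 5 structures,
scale-2 degradation, 16x16 patches at stride 8, a (5,3,3)-kernel network
with 8/8 hidden channels trained with MSE + Adam (lr 3e-3) — are fixed
here once and reused by every training-dependent test, so the expensive
runs happen a single time per session.
"""

import numpy as np
import pytest

from srmri.optimizers import OptimizerConfig
from srmri.pipeline import TrainingConfig, make_phantom_dataset, train

DATASET_SEED = 3


@pytest.fixture(scope="session")
def phantom_dataset():
    """(train PatchSet, validation pairs) under the desk-scale conditions."""
    return make_phantom_dataset(
        n_images=12, image_size=48, patch_size=16, stride=8, seed=DATASET_SEED
    )


@pytest.fixture(scope="session")
def desk_config():
    """Canonical three-stage network, MSE + Adam, desk-scale sizes."""
    return TrainingConfig(
        kernel_sizes=(5, 3, 3),
        channels=(8, 8),
        patch_size=16,
        stride=8,
        epochs=80,
        batch_size=16,
        eval_interval=100,
        seed=DATASET_SEED,
        optimizer=OptimizerConfig(kind="adam", learning_rate=3e-3),
    )


@pytest.fixture(scope="session")
def trained_run(phantom_dataset, desk_config):
    """(model, history) of the standard desk-scale MSE training run."""
    train_set, val_pairs = phantom_dataset
    return train(desk_config, train_set, val_pairs)


@pytest.fixture(scope="session")
def loss_histories(phantom_dataset, desk_config):
    """Validation-PSNR histories of the three losses under identical
    conditions (shorter runs: 40 epochs each)."""
    from dataclasses import replace

    train_set, val_pairs = phantom_dataset
    out = {}
    for kind in ("mse", "cross_entropy", "log_likelihood"):
        cfg = replace(desk_config, loss_kind=kind, epochs=40)
        _, hist = train(cfg, train_set, val_pairs)
        out[kind] = hist
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
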