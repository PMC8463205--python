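"""High-level modelling interface.

`SuperResolution` is built from data (a training patch set plus held-out
validation pairs, or directly from the phantom generator), `fit()` runs
the training loop and returns a `SuperResolutionResults` carrying the
trained network, the loss/PSNR history, and evaluation/summary/plotting
methods — the statsmodels idiom of a Model/Results pair.

Example
-------
>>> from srmri.model import SuperResolution
>>> sr = SuperResolution.from_phantoms(n_images=12, image_size=48, seed=7)
>>> res = sr.fit(epochs=4)
>>> print(res.summary())          # doctest: +SKIP
>>> hr_hat = res.predict(lr)      # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .metrics import MetricConfig, quality_report
from .network import SRCNNModel, forward
from .pipeline import (
    ComparisonReport,
    ImagePair,
    TrainingConfig,
    TrainingHistory,
    compare_methods,
    make_phantom_dataset,
    plot_history,
    train,
)
from .preprocessing import PatchSet

__all__ = ["SuperResolution", "SuperResolutionResults"]


class SuperResolution:
    """Super-resolution reconstruction model bound to a training set.

    Parameters
    ----------
    train_set : PatchSet
        Aligned (lr, hr) training patches on the common grid.
    val_pairs : sequence of (lr, hr) image pairs
        Held-out whole images used for the validation-PSNR curve.
    config : TrainingConfig, optional
        Architecture and training hyperparameters; defaults to the
        canonical three-stage 9-1-5 network trained with MSE + Adam.
    """

    def __init__(
        self,
        train_set: PatchSet,
        val_pairs: Sequence[ImagePair],
        config: TrainingConfig | None = None,
    ) -> None:
        self.train_set = train_set
        self.val_pairs = list(val_pairs)
        self.config = config or TrainingConfig()

    @classmethod
    def from_phantoms(
        cls,
        n_images: int = 20,
        image_size: int = 64,
        seed: int = 0,
        config: TrainingConfig | None = None,
        **dataset_kwargs,
    ) -> "SuperResolution":
        """Build the model directly on a seeded phantom dataset."""
        config = config or TrainingConfig(seed=seed)
        train_set, val_pairs = make_phantom_dataset(
            n_images=n_images,
            image_size=image_size,
            seed=seed,
            patch_size=config.patch_size,
            stride=config.stride,
            **dataset_kwargs,
        )
        return cls(train_set, val_pairs, config)

    def fit(self, **overrides) -> "SuperResolutionResults":
        """Train the network; keyword overrides patch the config
        (e.g. ``fit(epochs=10, loss_kind="mse")``)."""
        config = replace(self.config, **overrides) if overrides else self.config
        network, history = train(config, self.train_set, self.val_pairs)
        return SuperResolutionResults(self, network, history, config)


class SuperResolutionResults:
    """Fitted network plus its training history and diagnostics."""

    def __init__(
        self,
        model: SuperResolution,
        network: SRCNNModel,
        history: TrainingHistory,
        config: TrainingConfig,
    ) -> None:
        self.model = model
        self.network = network
        self.history = history
        self.config = config

    def predict(self, lr: np.ndarray) -> np.ndarray:
        """Reconstruct one pre-upsampled low-resolution image, clipped to [0, 1]."""
        return np.clip(forward(self.network, lr), 0.0, 1.0)

    def evaluate(
        self, test_pairs: Sequence[ImagePair] | None = None, config: MetricConfig | None = None
    ) -> ComparisonReport:
        """PSNR/SSIM of the network vs cubic interpolation on held-out pairs
        (defaults to the model's validation pairs)."""
        pairs = test_pairs if test_pairs is not None else self.model.val_pairs
        return compare_methods(self.network, pairs, config)

    def plot_history(self, ax=None):
        return plot_history(self.history, labels=["validation PSNR"], ax=ax)

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.config
        arch = " -> ".join(
            f"{l.in_channels}x{l.kernel_size}x{l.kernel_size}x{l.out_channels}"
            + ("+ReLU" if l.apply_relu else "")
            for l in self.network.layers
        )
        lines = [
            "Super-Resolution CNN Results",
            "=" * 60,
            f"architecture:        {arch}",
            f"parameters:          {self.network.n_parameters}",
            f"loss:                {cfg.loss_kind}",
            f"optimizer:           {cfg.optimizer.kind} (lr={cfg.optimizer.alpha:g})",
            f"epochs:              {cfg.epochs}",
            f"training patches:    {len(self.model.train_set)} "
            f"({cfg.patch_size}x{cfg.patch_size}, stride {cfg.stride})",
            f"validation images:   {len(self.model.val_pairs)}",
            f"seed / config hash:  {cfg.seed} / {cfg.config_hash}",
        ]
        if len(self.history):
            lines += [
                "-" * 60,
                f"iterations:          {self.history.iterations[-1]}",
                f"initial loss:        {self.history.loss[0]:.6g}",
                f"final loss:          {self.history.loss[-1]:.6g}",
                f"initial val PSNR:    {self.history.val_psnr[0]:.2f} dB",
                f"final val PSNR:      {self.history.val_psnr[-1]:.2f} dB",
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        n_it = self.history.iterations[-1] if len(self.history) else 0
        return f"<SuperResolutionResults: {n_it} iterations, {self.network.n_parameters} parameters>"
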