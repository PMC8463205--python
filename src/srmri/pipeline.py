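"""End-to-end training and evaluation harness.

Assembles phantom datasets, trains the reconstruction network by
minibatch gradient descent (forward pass, analytic backward pass,
optimizer step), logs training-loss and validation-PSNR curves, and
compares the trained model against the cubic-spline interpolation
baseline on held-out images. Everything is driven by one serializable
:class:`TrainingConfig`; two runs with the same config produce identical
histories.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigurationError, TrainingError
from .metrics import MetricConfig, psnr, ssim
from .network import SRCNNModel, backward_batch, forward
from .optimizers import OptimizerConfig, init_state, step
from .phantoms import DegradationSpec, PhantomSpec, degrade, generate_phantom, spline_upsample
from .preprocessing import PatchSet, augment, extract_patches, normalize

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "ComparisonReport",
    "train",
    "upscale_baseline",
    "compare_methods",
    "kernel_sweep",
    "make_phantom_dataset",
    "plot_history",
]

ImagePair = tuple[np.ndarray, np.ndarray]  # (lr on target grid, hr)


@dataclass(frozen=True)
class TrainingConfig:
    """Everything a training run depends on, in one serializable record."""

    loss_kind: str = "mse"
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    epochs: int = 30
    batch_size: int = 16
    patch_size: int = 32
    stride: int = 16
    kernel_sizes: tuple[int, ...] = (9, 1, 5)
    channels: tuple[int, ...] = (64, 32)
    seed: int = 0
    eval_interval: int = 10

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size < 1 or self.eval_interval < 1:
            raise ConfigurationError("batch_size and eval_interval must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        d = dict(d)
        if "optimizer" in d and isinstance(d["optimizer"], dict):
            d["optimizer"] = OptimizerConfig(**d["optimizer"])
        for key in ("kernel_sizes", "channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class TrainingHistory:
    """Training loss and validation PSNR sampled every evaluation interval."""

    iterations: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)

    def append(self, iteration: int, loss: float, val_psnr: float) -> None:
        self.iterations.append(int(iteration))
        self.loss.append(float(loss))
        self.val_psnr.append(float(val_psnr))

    def __len__(self) -> int:
        return len(self.iterations)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": self.iterations, "loss": self.loss, "val_psnr": self.val_psnr}
        )


def _validation_psnr(model: SRCNNModel, val_pairs: Sequence[ImagePair]) -> float:
    vals = []
    for lr, hr in val_pairs:
        recon = np.clip(forward(model, lr), 0.0, 1.0)
        vals.append(psnr(hr, recon))
    return float(np.mean(vals))


def train(
    config: TrainingConfig,
    train_set: PatchSet,
    val_pairs: Sequence[ImagePair],
) -> tuple[SRCNNModel, TrainingHistory]:
    """Train a freshly initialized model on the patch set.

    Runs ``epochs`` passes of seeded-shuffle minibatches; each iteration
    does one forward/backward pass and one optimizer step. The history
    records the minibatch loss and mean validation PSNR at iteration 0
    and every ``eval_interval`` iterations thereafter. Training is
    deterministic given the config (the single seed drives both the
    initialization and the shuffling).

    Raises
    ------
    TrainingError
        If the loss becomes non-finite, naming the iteration.
    """
    if len(train_set) == 0 or len(val_pairs) == 0:
        raise ConfigurationError("train set and validation pairs must be non-empty")
    model = SRCNNModel.build(config.kernel_sizes, config.channels, seed=config.seed)
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    shuffle_rng = np.random.default_rng((config.seed, 0x5EED))
    params = [p.copy() for p in model.parameters()]
    model.set_parameters(params)
    state = init_state(params)
    n = len(train_set)
    bs = min(config.batch_size, n)
    # iteration-0 snapshot: loss of the first forward pass, untrained PSNR
    first_idx = np.arange(bs)
    x0 = train_set.lr[first_idx][:, None]
    t0 = train_set.hr[first_idx][:, None]
    _, loss0 = backward_batch(model, x0, t0, config.loss_kind)
    history.append(0, loss0, _validation_psnr(model, val_pairs))
    iteration = 0
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            x = train_set.lr[idx][:, None]
            t = train_set.hr[idx][:, None]
            grads, loss = backward_batch(model, x, t, config.loss_kind)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at iteration {iteration + 1}")
            params, state = step(params, grads.flat(), state, config.optimizer)
            model.set_parameters(params)
            iteration += 1
            if iteration % config.eval_interval == 0:
                history.append(iteration, loss, _validation_psnr(model, val_pairs))
    if history.iterations[-1] != iteration:
        grads, loss = backward_batch(model, x, t, config.loss_kind)
        history.append(iteration, loss, _validation_psnr(model, val_pairs))
    return model, history


def upscale_baseline(lr_native: np.ndarray, scale_factor: int) -> np.ndarray:
    """Cubic-spline interpolation of a native-resolution image onto the
    target grid — the classical non-learned comparator."""
    lr_native = np.asarray(lr_native, dtype=np.float64)
    if scale_factor < 1:
        raise ConfigurationError("scale_factor must be >= 1")
    if scale_factor == 1:
        return lr_native.copy()
    out_shape = (lr_native.shape[0] * scale_factor, lr_native.shape[1] * scale_factor)
    return spline_upsample(lr_native, out_shape, scale_factor, order=3)


@dataclass
class ComparisonReport:
    """Per-method mean +/- sd PSNR and mean SSIM over a held-out set."""

    methods: dict[str, dict[str, float]]
    n_images: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.methods).T

    def __str__(self) -> str:
        lines = [f"held-out images: {self.n_images}"]
        for name, s in self.methods.items():
            lines.append(
                f"{name}: PSNR {s['psnr_mean']:.2f} +/- {s['psnr_sd']:.2f} dB, "
                f"SSIM {s['ssim_mean']:.4f}"
            )
        return "\n".join(lines)


def compare_methods(
    model: SRCNNModel | None,
    test_pairs: Sequence[ImagePair],
    config: MetricConfig | None = None,
    extra_reconstructions: dict[str, Sequence[np.ndarray]] | None = None,
) -> ComparisonReport:
    """Evaluate the trained network against cubic interpolation.

    Under the pre-upsampling convention the ``lr`` member of each pair is
    already the cubic-spline reconstruction, so the baseline column
    scores ``lr`` itself; the network column scores ``forward(model, lr)``
    clipped to [0, 1]. Externally produced reconstructions may be added
    as extra columns (one image per test pair).
    """
    if len(test_pairs) == 0:
        raise ConfigurationError("test set must be non-empty")
    cfg = config or MetricConfig()
    columns: dict[str, list[np.ndarray]] = {
        "cubic_interpolation": [lr for lr, _ in test_pairs]
    }
    if model is not None:
        columns["srcnn"] = [
            np.clip(forward(model, lr), 0.0, 1.0) for lr, _ in test_pairs
        ]
    for name, recons in (extra_reconstructions or {}).items():
        if len(recons) != len(test_pairs):
            raise ConfigurationError(
                f"method {name!r} supplies {len(recons)} images for {len(test_pairs)} pairs"
            )
        columns[name] = list(recons)
    methods = {}
    for name, recons in columns.items():
        psnrs = np.array([psnr(hr, r, cfg) for r, (_, hr) in zip(recons, test_pairs)])
        ssims = np.array([ssim(hr, r, cfg).ssim for r, (_, hr) in zip(recons, test_pairs)])
        methods[name] = {
            "psnr_mean": float(np.mean(psnrs)),
            "psnr_sd": float(np.std(psnrs)),
            "ssim_mean": float(np.mean(ssims)),
        }
    return ComparisonReport(methods, len(test_pairs))


def _config_for_count(base: TrainingConfig, count: int, mode: str) -> TrainingConfig:
    if mode == "depth":
        width = base.channels[0] if base.channels else 8
        first = base.kernel_sizes[0]
        last = base.kernel_sizes[-1]
        kernels = (first,) + (3,) * (count - 1) + (last,)
        channels = (width,) * count
        return replace(base, kernel_sizes=kernels, channels=channels)
    if mode == "width":
        return replace(base, channels=(count,) * len(base.channels))
    raise ConfigurationError(f"sweep mode must be 'depth' or 'width', got {mode!r}")


def kernel_sweep(
    base_config: TrainingConfig,
    kernel_counts: Sequence[int],
    train_set: PatchSet,
    val_pairs: Sequence[ImagePair],
    mode: str = "depth",
) -> list[TrainingHistory]:
    """Train one model per kernel count, everything else identical.

    The "number of convolution kernels" is exposed both as network depth
    (``mode='depth'``: ``count`` hidden layers of fixed width between the
    feature-extraction and reconstruction layers) and as width
    (``mode='width'``: ``count`` channels per hidden layer); depth is the
    default. Returns histories aligned with ``kernel_counts``.
    """
    if len(kernel_counts) == 0:
        raise ConfigurationError("kernel_counts must be non-empty")
    histories = []
    for count in kernel_counts:
        cfg = _config_for_count(base_config, int(count), mode)
        _, hist = train(cfg, train_set, val_pairs)
        histories.append(hist)
    return histories


def make_phantom_dataset(
    n_images: int = 20,
    image_size: int = 64,
    n_structures: int = 5,
    blur_sigma: float = 1.0,
    noise_model: str = "none",
    noise_sigma: float = 0.0,
    degradation: DegradationSpec | None = None,
    patch_size: int = 16,
    stride: int = 8,
    train_frac: float = 0.8,
    augment_data: bool = False,
    seed: int = 0,
) -> tuple[PatchSet, list[ImagePair]]:
    """Seeded phantom dataset: training patches plus held-out image pairs.

    Generates ``n_images`` normalized phantoms, degrades each to its
    pre-upsampled low-resolution counterpart, extracts aligned patches
    from the first ``train_frac`` of the images, and returns the
    remaining images whole as (lr, hr) validation pairs.
    """
    deg = degradation or DegradationSpec(scale_factor=2)
    pairs: list[ImagePair] = []
    for i in range(n_images):
        spec = PhantomSpec(
            height=image_size,
            width=image_size,
            n_structures=n_structures,
            blur_sigma=blur_sigma,
            noise_model=noise_model,
            noise_sigma=noise_sigma,
            seed=int(np.random.default_rng((seed, i)).integers(0, 2**31 - 1)),
        )
        hr = normalize(generate_phantom(spec))
        lr = degrade(hr, deg)
        pairs.append((lr, hr))
    n_train = max(1, int(round(train_frac * n_images)))
    if n_train >= n_images:
        n_train = n_images - 1
    lr_list, hr_list = [], []
    for lr, hr in pairs[:n_train]:
        ps = extract_patches(lr, hr, patch_size, stride)
        lr_list.append(ps.lr)
        hr_list.append(ps.hr)
    train_set = PatchSet(
        np.concatenate(lr_list), np.concatenate(hr_list), patch_size, stride
    )
    if augment_data:
        train_set = augment(train_set, seed=seed)
    return train_set, pairs[n_train:]


def plot_history(
    histories: TrainingHistory | Sequence[TrainingHistory],
    labels: Sequence[str] | None = None,
    ax=None,
):
    """Plot validation-PSNR training curves (one line per history)."""
    import matplotlib.pyplot as plt

    if isinstance(histories, TrainingHistory):
        histories = [histories]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, hist in enumerate(histories):
        label = labels[i] if labels else f"run {i}"
        ax.plot(hist.iterations, hist.val_psnr, label=label)
    ax.set_xlabel("iteration")
    ax.set_ylabel("validation PSNR (dB)")
    ax.legend()
    return ax
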