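"""The three-stage super-resolution convolutional network.

The model is the classic SRCNN layout: a feature-extraction convolution,
one or more nonlinear mapping convolutions, and a reconstruction
convolution, all operating on an input that has already been interpolated
to the target grid, so every layer preserves spatial size ("same" zero
padding). Convolution is implemented as cross-correlation (no kernel
flip), the CNN convention. Each hidden layer is followed by a ReLU;
the reconstruction layer is linear.

Gradients are hand-derived, not autodiff: the backward pass propagates
the loss derivative through the linear reconstruction, the ReLU masks
(subgradient 0 at 0), and the convolution adjoints, producing analytic
gradients for every kernel weight and bias. Correctness is established
by central finite differences in the test-suite.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as _losses
from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "ConvLayer",
    "SRCNNModel",
    "GradientSet",
    "relu",
    "conv_forward",
    "forward",
    "backward",
]


def relu(x):
    """Rectified linear unit, elementwise: x for x >= 0, else 0."""
    return np.maximum(x, 0.0)


@dataclass
class ConvLayer:
    """One convolution layer.

    weights : (out_channels, in_channels, k, k) array; k odd so "same"
        zero padding is symmetric.
    bias : (out_channels,) array.
    apply_relu : whether the ReLU nonlinearity follows the convolution.
    """

    weights: np.ndarray
    bias: np.ndarray
    apply_relu: bool = True

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.weights.ndim != 4:
            raise ShapeError("weights must be 4-D (out, in, k, k)")
        kh, kw = self.weights.shape[2:]
        if kh % 2 == 0 or kw % 2 == 0:
            raise ShapeError(f"kernel dimensions must be odd, got {kh}x{kw}")
        if self.bias.shape != (self.weights.shape[0],):
            raise ShapeError(
                f"bias length {self.bias.shape} must equal out_channels {self.weights.shape[0]}"
            )

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[2]


def _conv_bchw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlate a (B, C, H, W) stack with (O, C, kh, kw) kernels,
    zero "same" padding, returning (B, O, H, W).

    Implemented as a shift-and-accumulate over kernel offsets; each offset
    is one (O, C) x (B, C, H, W) contraction, which keeps the memory
    footprint at one padded copy of the input."""
    b, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ShapeError(f"input has {c} channels but kernels expect {ci}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    out = np.zeros((b, o, h, wd), dtype=np.float64)
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u : u + h, v : v + wd]
            out += np.einsum("oc,bchw->bohw", w[:, :, u, v], xs, optimize=True)
    return out


def _conv_weight_grad(x: np.ndarray, delta: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Gradient of the convolution output w.r.t. the kernels:
    dL/dw[o,c,u,v] = sum_{b,i,j} delta[b,o,i,j] * x_padded[b,c,i+u,j+v]."""
    b, c, h, wd = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    o = delta.shape[1]
    dw = np.empty((o, c, kh, kw), dtype=np.float64)
    for u in range(kh):
        for v in range(kw):
            xs = xp[:, :, u : u + h, v : v + wd]
            dw[:, :, u, v] = np.einsum("bohw,bchw->oc", delta, xs, optimize=True)
    return dw


def _conv_input_grad(delta: np.ndarray, w: np.ndarray, in_shape) -> np.ndarray:
    """Adjoint of the padded cross-correlation: scatter each offset's
    contribution back into a padded buffer, then crop the padding."""
    b, o, h, wd = delta.shape
    oc, c, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((b, c, h + 2 * ph, wd + 2 * pw), dtype=np.float64)
    for u in range(kh):
        for v in range(kw):
            dxp[:, :, u : u + h, v : v + wd] += np.einsum(
                "oc,bohw->bchw", w[:, :, u, v], delta, optimize=True
            )
    return dxp[:, :, ph : ph + h, pw : pw + wd]


def conv_forward(x: np.ndarray, layer: ConvLayer) -> np.ndarray:
    """Forward one layer on a (C, H, W) stack (or a bare (H, W) image):
    cross-correlation with "same" zero padding, per-channel bias, then
    ReLU iff ``layer.apply_relu``. Output spatial size equals input."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ShapeError(f"expected (C, H, W) input, got shape {x.shape}")
    out = _conv_bchw(x[None], layer.weights)[0] + layer.bias[:, None, None]
    return relu(out) if layer.apply_relu else out


@dataclass
class SRCNNModel:
    """Ordered convolution layers; the last layer reconstructs 1 channel
    with no ReLU."""

    layers: list[ConvLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ConfigurationError("model needs at least one layer")
        for a, b in zip(self.layers, self.layers[1:]):
            if a.out_channels != b.in_channels:
                raise ShapeError(
                    f"layer outputs {a.out_channels} channels but next expects {b.in_channels}"
                )
        last = self.layers[-1]
        if last.out_channels != 1:
            raise ConfigurationError("final layer must output 1 channel")
        if last.apply_relu:
            raise ConfigurationError("final (reconstruction) layer must be linear")

    @classmethod
    def build(
        cls,
        kernel_sizes: tuple[int, ...] = (9, 1, 5),
        channels: tuple[int, ...] = (64, 32),
        seed: int = 0,
        scale: float | None = None,
    ) -> "SRCNNModel":
        """He-initialized model: zero-mean Gaussian weights with variance
        2 / fan-in (ReLU-appropriate), biases zero, all from one seed.

        ``len(kernel_sizes)`` is the layer count; ``channels`` gives the
        hidden widths (one fewer entry than kernels). The default 9-1-5
        with 64/32 channels is the canonical three-stage configuration.
        """
        if len(kernel_sizes) != len(channels) + 1:
            raise ConfigurationError(
                "need len(kernel_sizes) == len(channels) + 1 "
                f"(got {len(kernel_sizes)} kernels, {len(channels)} widths)"
            )
        rng = np.random.default_rng(seed)
        widths = (1, *channels, 1)
        layers = []
        n = len(kernel_sizes)
        for i, k in enumerate(kernel_sizes):
            cin, cout = widths[i], widths[i + 1]
            fan_in = cin * k * k
            std = scale if scale is not None else np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(cout, cin, k, k))
            layers.append(ConvLayer(w, np.zeros(cout), apply_relu=(i < n - 1)))
        return cls(layers)

    def parameters(self) -> list[np.ndarray]:
        """Flat parameter list [w1, b1, w2, b2, ...] (views, not copies)."""
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.append(layer.weights)
            out.append(layer.bias)
        return out

    def set_parameters(self, params: list[np.ndarray]) -> None:
        if len(params) != 2 * len(self.layers):
            raise ShapeError("parameter list length mismatch")
        for i, layer in enumerate(self.layers):
            w, b = params[2 * i], params[2 * i + 1]
            if w.shape != layer.weights.shape or b.shape != layer.bias.shape:
                raise ShapeError("parameter shape mismatch")
            layer.weights = np.asarray(w, dtype=np.float64)
            layer.bias = np.asarray(b, dtype=np.float64)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def copy(self) -> "SRCNNModel":
        return SRCNNModel(
            [
                ConvLayer(l.weights.copy(), l.bias.copy(), l.apply_relu)
                for l in self.layers
            ]
        )

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path, metadata: dict | None = None) -> None:
        """Single-archive checkpoint: layer arrays plus JSON metadata."""
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            arrays[f"w{i}"] = layer.weights
            arrays[f"b{i}"] = layer.bias
        np.savez(path, **arrays)
        meta = {
            "n_layers": len(self.layers),
            "kernel_sizes": [l.kernel_size for l in self.layers],
            "channels": [l.out_channels for l in self.layers[:-1]],
            **(metadata or {}),
        }
        with zipfile.ZipFile(path if path.suffix == ".npz" else path.with_suffix(".npz"), "a") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "SRCNNModel":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
        npz = np.load(path)
        n = meta["n_layers"]
        layers = [
            ConvLayer(npz[f"w{i}"], npz[f"b{i}"], apply_relu=(i < n - 1))
            for i in range(n)
        ]
        return cls(layers)


@dataclass
class GradientSet:
    """Per-layer (weight, bias) gradients, shapes mirroring the model."""

    weight_grads: list[np.ndarray]
    bias_grads: list[np.ndarray]

    def flat(self) -> list[np.ndarray]:
        """Same ordering as :meth:`SRCNNModel.parameters`."""
        out: list[np.ndarray] = []
        for dw, db in zip(self.weight_grads, self.bias_grads):
            out.append(dw)
            out.append(db)
        return out


def _forward_batch(model: SRCNNModel, x: np.ndarray):
    """Forward a (B, 1, H, W) batch; returns (activations, pre_activations)
    with activations[0] = input and activations[-1] = prediction."""
    acts = [x]
    pres = []
    for layer in model.layers:
        z = _conv_bchw(acts[-1], layer.weights) + layer.bias[None, :, None, None]
        pres.append(z)
        acts.append(relu(z) if layer.apply_relu else z)
    return acts, pres


def forward(model: SRCNNModel, lr: np.ndarray) -> np.ndarray:
    """Reconstruct a single normalized image; output has the input's size."""
    lr = np.asarray(lr, dtype=np.float64)
    if lr.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {lr.shape}")
    acts, _ = _forward_batch(model, lr[None, None])
    return acts[-1][0, 0]


def backward_batch(
    model: SRCNNModel, x: np.ndarray, targets: np.ndarray, loss_kind: str = "mse"
) -> tuple[GradientSet, float]:
    """Loss and analytic gradients for a (B, 1, H, W) batch.

    The scalar loss treats all batch pixels as one flat sample of size
    m = B*H*W, matching the loss definitions; gradients follow by the
    chain rule through the ReLU masks and the convolution adjoints.
    """
    acts, pres = _forward_batch(model, x)
    pred = acts[-1]
    loss = _losses.loss_value(pred, targets, loss_kind)
    dpred = _losses.loss_gradient(pred, targets, loss_kind).reshape(pred.shape)
    delta = dpred
    n = len(model.layers)
    wgrads: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    bgrads: list[np.ndarray] = [None] * n  # type: ignore[list-item]
    for i in range(n - 1, -1, -1):
        layer = model.layers[i]
        if layer.apply_relu:
            delta = delta * (pres[i] > 0)
        wgrads[i] = _conv_weight_grad(
            acts[i], delta, layer.weights.shape[2], layer.weights.shape[3]
        )
        bgrads[i] = delta.sum(axis=(0, 2, 3))
        if i > 0:
            delta = _conv_input_grad(delta, layer.weights, acts[i].shape)
    return GradientSet(wgrads, bgrads), loss


def backward(
    model: SRCNNModel, lr: np.ndarray, target: np.ndarray, loss_kind: str = "mse"
) -> GradientSet:
    """Analytic gradients of the scalar loss for one (lr, target) pair."""
    lr = np.asarray(lr, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if lr.shape != target.shape or lr.ndim != 2:
        raise ShapeError("lr and target must be 2-D images of equal shape")
    grads, _ = backward_batch(model, lr[None, None], target[None, None], loss_kind)
    return grads
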