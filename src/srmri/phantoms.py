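"""Synthetic MRI-like phantoms and the low-resolution degradation model.

Real knee-MRI slices are piecewise-smooth, band-limited images of soft-tissue
structures on a dark background. The phantom generator emulates that
statistical character with overlapping smooth ellipses and optional annuli
(crude meniscus-like crescents) so the full super-resolution pipeline can be
exercised without any acquisition data. Magnitude MRI noise is Rician, so a
Rician option is provided alongside additive Gaussian noise; the default is
noise-free.

The degradation model follows the standard single-image super-resolution
convention: Gaussian pre-blur, decimation by an integer factor, and spline
re-upsampling back to the original grid ("pre-upsampling"), so the network
input and the high-resolution target share one pixel grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, ShapeError

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "generate_phantom",
    "degrade",
    "spline_upsample",
]

_NOISE_MODELS = ("none", "gaussian", "rician")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic high-resolution phantom.

    Parameters
    ----------
    height, width : int
        Image dimensions in pixels (>= 16). Default 256x256, the matrix
        size typical of clinical knee MRI.
    n_structures : int
        Number of elliptical/annular components (>= 1).
    intensity_range : (float, float)
        Closed interval in [0, 1] from which structure plateau intensities
        are drawn; low <= high.
    blur_sigma : float
        Gaussian smoothing applied to the clean phantom, in pixels (>= 0).
        Makes edges band-limited, as in real reconstructions.
    noise_model : {"none", "gaussian", "rician"}
    noise_sigma : float
        Noise scale in intensity units (>= 0).
    seed : int
        Single seed from which all randomness flows.
    """

    height: int = 256
    width: int = 256
    n_structures: int = 6
    intensity_range: tuple[float, float] = (0.3, 0.9)
    blur_sigma: float = 1.5
    noise_model: str = "none"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ConfigurationError(
                f"phantom dimensions must be >= 16, got {self.height}x{self.width}"
            )
        if self.n_structures < 1:
            raise ConfigurationError("n_structures must be >= 1")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= 1.0) or (lo == hi == 0.0):
            raise ConfigurationError(
                f"intensity_range must satisfy 0 <= low <= high <= 1, got {self.intensity_range}"
            )
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")
        if self.noise_model not in _NOISE_MODELS:
            raise ConfigurationError(
                f"noise_model must be one of {_NOISE_MODELS}, got {self.noise_model!r}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class DegradationSpec:
    """Low-resolution degradation: blur -> decimate -> spline re-upsample.

    ``pre_blur_sigma=None`` uses the conventional ``scale_factor / 2``.
    ``interp_order`` is the order of the spline used for the re-upsampling
    step (0 = nearest, 1 = linear, 3 = cubic).
    """

    scale_factor: int = 2
    pre_blur_sigma: float | None = None
    interp_order: int = 3

    def __post_init__(self) -> None:
        if self.scale_factor < 1:
            raise ConfigurationError("scale_factor must be >= 1")
        if self.pre_blur_sigma is not None and self.pre_blur_sigma < 0:
            raise ConfigurationError("pre_blur_sigma must be >= 0")
        if self.interp_order not in (0, 1, 3, 5):
            raise ConfigurationError("interp_order must be one of 0, 1, 3, 5")

    @property
    def blur_sigma(self) -> float:
        if self.pre_blur_sigma is None:
            return self.scale_factor / 2.0
        return self.pre_blur_sigma


def _ellipse_mask(
    h: int, w: int, cy: float, cx: float, ay: float, ax: float, angle: float
) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate one seeded high-resolution phantom in [0, 1].

    Structures are drawn as filled ellipses (about one in three rendered as
    an annulus) with constant plateau intensity; overlaps combine by
    maximum so plateaus stay flat. Blur and noise are applied afterwards
    and the result is clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.zeros((h, w), dtype=np.float64)
    lo, hi = spec.intensity_range
    for _ in range(spec.n_structures):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        ay = rng.uniform(0.06, 0.28) * min(h, w)
        ax = rng.uniform(0.06, 0.28) * min(h, w)
        angle = rng.uniform(0.0, np.pi)
        intensity = rng.uniform(lo, hi)
        mask = _ellipse_mask(h, w, cy, cx, ay, ax, angle)
        if rng.uniform() < 0.3:
            inner = _ellipse_mask(h, w, cy, cx, 0.6 * ay, 0.6 * ax, angle)
            mask = mask & ~inner
        img = np.maximum(img, intensity * mask)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, spec.blur_sigma, mode="constant")
    if spec.noise_model == "gaussian" and spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    elif spec.noise_model == "rician" and spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, size=img.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, size=img.shape)
        img = np.sqrt((img + n1) ** 2 + n2**2)
    return np.clip(img, 0.0, 1.0)


def spline_upsample(
    lr: np.ndarray, out_shape: tuple[int, int], scale: int, order: int = 3
) -> np.ndarray:
    """Interpolate a decimated image back onto the original grid.

    Low-resolution pixel ``i`` sits at high-resolution coordinate
    ``i * scale`` (the grid used by ``x[::scale]`` decimation); values at
    the remaining coordinates come from a tensor-product not-a-knot
    B-spline of the given order, with polynomial extrapolation past the
    last sample.
    """
    if order == 0:
        up = np.repeat(np.repeat(lr, scale, axis=0), scale, axis=1)
        return up[: out_shape[0], : out_shape[1]]
    out = np.asarray(lr, dtype=np.float64)
    for axis in (0, 1):
        n = out.shape[axis]
        k = min(order, n - 1)
        xs = np.arange(n) * scale
        xt = np.arange(out_shape[axis], dtype=np.float64)
        out = make_interp_spline(xs, out, k=k, axis=axis)(xt)
    return out


def degrade(hr: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Produce the pre-upsampled low-resolution counterpart of ``hr``.

    Pipeline: Gaussian blur (``spec.blur_sigma``) -> decimate by
    ``scale_factor`` -> spline-interpolate back to the original size.
    Output is clipped to [0, 1] when the input lies in [0, 1].
    """
    hr = np.asarray(hr, dtype=np.float64)
    if hr.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {hr.shape}")
    s = spec.scale_factor
    if hr.shape[0] % s or hr.shape[1] % s:
        raise ShapeError(
            f"image shape {hr.shape} not divisible by scale_factor {s}"
        )
    if s == 1 and spec.blur_sigma == 0:
        return hr.copy()
    blurred = gaussian_filter(hr, spec.blur_sigma, mode="nearest") if spec.blur_sigma > 0 else hr
    lr = blurred[::s, ::s]
    up = spline_upsample(lr, hr.shape, s, spec.interp_order)
    lo, hi = float(hr.min()), float(hr.max())
    if 0.0 <= lo and hi <= 1.0:
        up = np.clip(up, 0.0, 1.0)
    return up
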