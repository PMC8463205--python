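"""Image-quality metrics: PSNR and single-scale SSIM.

PSNR is ``10 log10(L^2 / MSE)`` decibels, with L the peak signal value
(1.0 for normalized images, 255 for raw 8-bit). Identical images have
zero MSE and the sentinel ``+inf`` is returned, never a clipped finite
value.

SSIM multiplies three moment-based similarity components,

    luminance L = (2 mu_f mu_g + c1) / (mu_f^2 + mu_g^2 + c1)
    contrast  C = (2 sg_f sg_g + c2) / (sg_f^2 + sg_g^2 + c2)
    structure S = (cov_fg + c3) / (sg_f sg_g + c3)

with c1 = (k1 R)^2, c2 = (k2 R)^2, c3 = c2/2, R the pixel value range,
k1 = 0.01, k2 = 0.03, and unit exponents by default. The statistics are
population moments (divide by N). The default window is the whole image
("global"); an 8x8 uniform sliding window that averages per-window SSIM
over all fully-interior positions is provided for comparison with common
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, ShapeError

__all__ = ["MetricConfig", "QualityReport", "psnr", "ssim", "quality_report", "write_report"]


@dataclass(frozen=True)
class MetricConfig:
    """Peak value, dynamic range, stability constants and exponents.

    ``L`` is the PSNR peak signal; ``R`` the SSIM pixel-value range. Both
    default to 1.0 because pipeline images are max-normalized; use 255
    for raw 8-bit inputs. ``c3`` is maintained as ``c2 / 2``.
    """

    L: float = 1.0
    R: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    window: str = "global"
    window_size: int = 8

    def __post_init__(self) -> None:
        if self.L <= 0 or self.R <= 0:
            raise ConfigurationError("L and R must be > 0")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ConfigurationError("k1 and k2 must be > 0")
        if self.window not in ("global", "sliding"):
            raise ConfigurationError("window must be 'global' or 'sliding'")
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")

    @property
    def c1(self) -> float:
        return (self.k1 * self.R) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.R) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


@dataclass(frozen=True)
class QualityReport:
    """PSNR (dB) plus SSIM and its components (window means when sliding)."""

    psnr: float
    ssim: float
    luminance: float
    contrast: float
    structure: float


def _check_pair(f, g) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise ShapeError(f"image shapes differ: {f.shape} vs {g.shape}")
    if f.ndim != 2:
        raise ShapeError("expected 2-D images")
    return f, g


def psnr(f, g, config: MetricConfig | None = None) -> float:
    """Peak signal-to-noise ratio in decibels; ``+inf`` for identical images."""
    config = config or MetricConfig()
    f, g = _check_pair(f, g)
    mse = float(np.mean((f - g) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(config.L**2 / mse)


def _ssim_components(mu_f, mu_g, var_f, var_g, cov, cfg: MetricConfig):
    sg_f = np.sqrt(var_f)
    sg_g = np.sqrt(var_g)
    lum = (2.0 * mu_f * mu_g + cfg.c1) / (mu_f**2 + mu_g**2 + cfg.c1)
    con = (2.0 * sg_f * sg_g + cfg.c2) / (var_f + var_g + cfg.c2)
    struct = (cov + cfg.c3) / (sg_f * sg_g + cfg.c3)
    total = lum**cfg.alpha * con**cfg.beta * struct**cfg.gamma
    return lum, con, struct, total


def ssim(f, g, config: MetricConfig | None = None) -> QualityReport:
    """Structural similarity between ``f`` and ``g``.

    Global window: one set of whole-image moments; the report satisfies
    ``ssim == luminance**alpha * contrast**beta * structure**gamma``.
    Sliding window: per-window statistics on every fully-interior uniform
    window, with the means over windows reported.
    """
    cfg = config or MetricConfig()
    f, g = _check_pair(f, g)
    p = psnr(f, g, cfg)
    if cfg.window == "global":
        mu_f, mu_g = f.mean(), g.mean()
        var_f, var_g = f.var(), g.var()
        cov = float(np.mean((f - mu_f) * (g - mu_g)))
        lum, con, struct, total = _ssim_components(mu_f, mu_g, var_f, var_g, cov, cfg)
        return QualityReport(p, float(total), float(lum), float(con), float(struct))
    w = cfg.window_size
    if w > min(f.shape):
        raise ShapeError(f"window_size {w} exceeds image shape {f.shape}")
    fw = sliding_window_view(f, (w, w))
    gw = sliding_window_view(g, (w, w))
    mu_f = fw.mean(axis=(-2, -1))
    mu_g = gw.mean(axis=(-2, -1))
    var_f = fw.var(axis=(-2, -1))
    var_g = gw.var(axis=(-2, -1))
    cov = (fw * gw).mean(axis=(-2, -1)) - mu_f * mu_g
    lum, con, struct, total = _ssim_components(mu_f, mu_g, var_f, var_g, cov, cfg)
    return QualityReport(
        p, float(total.mean()), float(lum.mean()), float(con.mean()), float(struct.mean())
    )


def quality_report(f, g, config: MetricConfig | None = None) -> QualityReport:
    """PSNR and SSIM of one image pair in a single report."""
    return ssim(f, g, config)


def write_report(
    reports: dict[str, QualityReport], path: str | Path, config: MetricConfig | None = None
) -> None:
    """Write a batch of quality reports as CSV (one row per image id)."""
    import hashlib
    import pandas as pd

    cfg = config or MetricConfig()
    cfg_hash = hashlib.sha1(repr(cfg).encode()).hexdigest()[:12]
    rows = [
        {
            "image_id": key,
            "psnr_db": r.psnr,
            "ssim": r.ssim,
            "luminance": r.luminance,
            "contrast": r.contrast,
            "structure": r.structure,
            "config_hash": cfg_hash,
        }
        for key, r in reports.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
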