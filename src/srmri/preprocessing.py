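"""Image normalization, training-patch extraction, and augmentation.

Normalization divides every pixel by the per-image maximum, so each image
is referenced to a peak of 1. Patch extraction slides a square window on a
stride grid over an aligned (low-resolution, high-resolution) image pair —
both already on the same grid under the pre-upsampling convention — and
augmentation expands each pair with the 8 dihedral variants (flips and
quarter-turn rotations), the standard enrichment for super-resolution
training sets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import DegenerateInputError, ShapeError

__all__ = ["PatchSet", "normalize", "extract_patches", "augment"]


@dataclass
class PatchSet:
    """Aligned low-/high-resolution training patches.

    ``lr`` and ``hr`` are (n, p, p) arrays aligned 1:1 (patch ``i`` of
    ``lr`` is the network input whose target is patch ``i`` of ``hr``).
    """

    lr: np.ndarray
    hr: np.ndarray
    patch_size: int
    stride: int

    def __post_init__(self) -> None:
        if self.lr.shape != self.hr.shape:
            raise ShapeError(
                f"lr patches {self.lr.shape} and hr patches {self.hr.shape} must align"
            )
        if self.lr.ndim != 3:
            raise ShapeError("patch arrays must be 3-D (n, p, p)")

    def __len__(self) -> int:
        return self.lr.shape[0]

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz with a JSON manifest alongside."""
        path = Path(path)
        np.savez(path, lr=self.lr, hr=self.hr)
        manifest = {
            "patch_size": self.patch_size,
            "stride": self.stride,
            "n_patches": len(self),
            "lr_sha1": hashlib.sha1(self.lr.tobytes()).hexdigest(),
            "hr_sha1": hashlib.sha1(self.hr.tobytes()).hexdigest(),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PatchSet":
        path = Path(path)
        npz = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        manifest = json.loads(path.with_suffix(".json").read_text())
        return cls(npz["lr"], npz["hr"], manifest["patch_size"], manifest["stride"])


def normalize(raw: np.ndarray) -> np.ndarray:
    """Divide every pixel by the image maximum so the peak equals 1.

    Raises
    ------
    DegenerateInputError
        If the image has no strictly positive pixel (division by zero) or
        contains negative intensities.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0 or np.any(raw < 0):
        raise DegenerateInputError("image must be non-empty with non-negative pixels")
    peak = raw.max()
    if peak <= 0:
        raise DegenerateInputError("cannot normalize an all-zero image")
    return raw / peak


def extract_patches(
    lr: np.ndarray, hr: np.ndarray, patch_size: int = 32, stride: int = 16
) -> PatchSet:
    """All axis-aligned patches on the stride grid, in row-major order.

    The count is ``(floor((H-p)/s)+1) * (floor((W-p)/s)+1)``.
    """
    lr = np.asarray(lr, dtype=np.float64)
    hr = np.asarray(hr, dtype=np.float64)
    if lr.shape != hr.shape:
        raise ShapeError(f"lr {lr.shape} and hr {hr.shape} must have equal shapes")
    if lr.ndim != 2:
        raise ShapeError("expected 2-D images")
    h, w = lr.shape
    if patch_size > h or patch_size > w:
        raise ShapeError(f"patch_size {patch_size} exceeds image shape {lr.shape}")
    if stride < 1:
        raise ShapeError("stride must be >= 1")
    lr_p = sliding_window_view(lr, (patch_size, patch_size))[::stride, ::stride]
    hr_p = sliding_window_view(hr, (patch_size, patch_size))[::stride, ::stride]
    n = lr_p.shape[0] * lr_p.shape[1]
    return PatchSet(
        lr_p.reshape(n, patch_size, patch_size).copy(),
        hr_p.reshape(n, patch_size, patch_size).copy(),
        patch_size,
        stride,
    )


def _dihedral(patches: np.ndarray) -> np.ndarray:
    """The 8 dihedral variants of each patch in a fixed order:
    identity, rot90, rot180, rot270, then the horizontal flip of each."""
    variants = []
    for k in range(4):
        rot = np.rot90(patches, k=k, axes=(1, 2))
        variants.append(rot)
        variants.append(rot[:, :, ::-1])
    return np.concatenate(variants, axis=0)


def augment(patches: PatchSet, seed: int | None = None) -> PatchSet:
    """Expand each pair with its 8 dihedral variants, lr and hr transformed
    identically. ``seed`` optionally shuffles the output order (it never
    changes the set of patches)."""
    lr8 = np.ascontiguousarray(_dihedral(patches.lr))
    hr8 = np.ascontiguousarray(_dihedral(patches.hr))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(lr8.shape[0])
        lr8, hr8 = lr8[order], hr8[order]
    return PatchSet(lr8, hr8, patches.patch_size, patches.stride)
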