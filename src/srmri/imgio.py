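"""Reading and writing grayscale images and raw arrays.

PNG/TIFF (8- or 16-bit grayscale) go through imageio; raw arrays are
stored as ``.npy`` with a JSON sidecar carrying provenance (for phantoms,
the generating :class:`~srmri.phantoms.PhantomSpec`).
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import ConfigurationError

__all__ = ["read_image", "write_image", "save_array", "load_array"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image and rescale integer dtypes to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) with the luminance average
        arr = arr[..., :3].mean(axis=-1)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def write_image(path: str | Path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale PNG/TIFF."""
    if bit_depth == 8:
        out = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.round(img * 65535.0), 0, 65535).astype(np.uint16)
    else:
        raise ConfigurationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(path, out)


def save_array(path: str | Path, img: np.ndarray, provenance: object | None = None) -> None:
    """Save a float array as .npy plus a JSON sidecar with provenance."""
    path = Path(path)
    np.save(path, np.asarray(img, dtype=np.float64))
    if provenance is not None:
        meta = asdict(provenance) if is_dataclass(provenance) else provenance
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(meta, indent=2, default=str))


def load_array(path: str | Path) -> tuple[np.ndarray, dict | None]:
    """Load an array saved by :func:`save_array`; returns (array, metadata)."""
    path = Path(path)
    arr = np.load(path if path.suffix == ".npy" else path.with_suffix(".npy"))
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return arr, meta
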