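"""Image reading/writing: 8-bit RGB as PNG or BMP, masks as 0/255 PNG."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]


def read_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image (PNG, BMP, ...) as an (H, W, 3) array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 array; format follows the extension
    (BMP stays uncompressed, PNG lossless)."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask: nonzero pixels are True."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as single-channel 0/255 PNG."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
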