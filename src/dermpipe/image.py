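"""Raster image container and lossless/lossy file I/O.

Images are plain ``numpy`` unsigned-integer arrays of shape ``(H, W)`` or
``(H, W, C)`` with ``C in {1, 3}``.  :class:`RasterImage` wraps such an array
together with its bit depth ``L`` (bits per channel, default 8) so that the
cipher can form the negative-positive complement ``2**L - 1`` without
guessing the dtype's width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class RasterImage:
    """An ``H x W [x C]`` unsigned-integer pixel array with bit depth ``L``."""

    pixels: np.ndarray
    bit_depth: int = 8
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixel array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise ValueError(f"channel count must be 1 or 3, got {px.shape[2]}")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixel dtype must be integer, got {px.dtype}")
        if self.bit_depth < 1 or self.bit_depth > 16:
            raise ValueError(f"bit depth must be in [1, 16], got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > self.max_value):
            raise ValueError(
                f"pixel values must lie in [0, {self.max_value}] for L={self.bit_depth}"
            )
        self.pixels = px

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy(), self.bit_depth, dict(self.metadata))


def load_image(path: str | Path) -> RasterImage:
    """Read a PNG/JPEG file into an 8-bit :class:`RasterImage` (RGB or grayscale)."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    return RasterImage(arr, bit_depth=8, metadata={"source": str(path)})


def save_image(img: RasterImage, path: str | Path, *, quality: int = 95) -> Path:
    """Write an image to disk.

    PNG is lossless and is the default carrier for ciphertext; JPEG is allowed
    but lossy, so a JPEG-stored ciphertext will not decrypt bit-exactly.
    """
    path = Path(path)
    arr = img.pixels
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    pil = Image.fromarray(arr.astype(np.uint8))
    if path.suffix.lower() in (".jpg", ".jpeg"):
        pil.save(path, quality=quality)
    else:
        pil.save(path)
    return path


def resize_to(pixels: np.ndarray, size: int) -> np.ndarray:
    """Bilinear-resize ``pixels`` to ``size x size`` and scale to float [0, 1]."""
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        arr = arr[:, :, None].repeat(3, axis=2)
    pil = Image.fromarray(arr.astype(np.uint8))
    out = pil.resize((size, size), Image.BILINEAR)
    return np.asarray(out, dtype=np.float64) / 255.0
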