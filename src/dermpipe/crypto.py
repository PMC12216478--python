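"""Block-scrambling-based encryption (BSBE) for raster images.

The cipher partitions an ``X x Y`` image into non-overlapping ``Bx x By``
blocks and applies four keyed, exactly invertible scrambling steps:

1. **Block permutation** (key stream K1): blocks are rearranged by a secret
   permutation of the row-major block order.
2. **Dihedral transform** (K2): each block is rotated/flipped by one of the
   8 symmetries of the square (4 rotations x optional horizontal flip).
3. **Negative-positive transform** (K3): where the per-block key bit
   ``r(i) = 1``, every pixel ``p`` becomes ``p XOR (2**L - 1)``; the bit has
   occurrence probability 0.5.  The same bit applies to all colour channels.
4. **Channel shuffle** (K4): the three colour components of each block are
   permuted by one of the 3! = 6 channel permutations.

Decryption applies the exact inverses in reverse order
(K4^-1, K3, K2^-1, K1^-1), so ``decrypt(encrypt(x)) == x`` bit for bit on any
lossless carrier (PNG).  Because the cipher only moves and complements whole
blocks, the ciphertext keeps block-local pixel statistics and remains
compressible by ordinary codecs (encryption-then-compression).

Key derivation (an artifact of this implementation — the scheme itself only
assumes the four streams exist): the four streams are drawn, in the fixed
order K1, K2, K3, K4, from a single ``numpy.random.Generator`` (PCG64) seeded
with the integer master seed.  The generator and stream order are part of the
file-format contract: two parties sharing the seed derive identical keys.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .image import RasterImage

#: The six permutations of (R, G, B) in lexicographic order; index 0 = identity.
CHANNEL_PERMUTATIONS: tuple[tuple[int, int, int], ...] = tuple(
    itertools.permutations(range(3))
)

#: Inverse index of each channel permutation.
_CHANNEL_INVERSE = tuple(
    CHANNEL_PERMUTATIONS.index(tuple(int(np.argsort(p)[k]) for k in range(3)))
    for p in CHANNEL_PERMUTATIONS
)


@dataclass(frozen=True)
class KeySet:
    """The four secret streams derived from one master seed.

    ``k1`` is a permutation of block indices, ``k2`` per-block dihedral
    indices in 0..7, ``k3`` per-block negative-positive bits, ``k4`` per-block
    channel-permutation indices in 0..5.
    """

    master_seed: int
    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    k4: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.k1)


@dataclass(frozen=True)
class BlockPartition:
    """Row-major tiling of a (possibly padded) image into ``bx x by`` blocks."""

    bx: int
    by: int
    n_rows: int  # blocks per column (vertical count)
    n_cols: int  # blocks per row (horizontal count)
    pad_bottom: int = 0
    pad_right: int = 0

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols


def derive_keys(master_seed: int, n_blocks: int) -> KeySet:
    """Derive the K1..K4 streams for ``n_blocks`` blocks from one seed.

    Deterministic: identical ``(master_seed, n_blocks)`` always yields the
    identical :class:`KeySet`.
    """
    if n_blocks < 1:
        raise ValueError(f"n_blocks must be >= 1, got {n_blocks}")
    rng = np.random.default_rng(np.random.SeedSequence(int(master_seed)))
    k1 = rng.permutation(n_blocks)
    k2 = rng.integers(0, 8, size=n_blocks)
    k3 = rng.integers(0, 2, size=n_blocks)
    k4 = rng.integers(0, 6, size=n_blocks)
    return KeySet(int(master_seed), k1, k2, k3, k4)


def partition_image(
    img: RasterImage, bx: int, by: int, *, pad: bool = False
) -> tuple[BlockPartition, list[np.ndarray]]:
    """Tile an image into ``bx x by`` blocks in row-major order.

    Dimensions must be divisible by the block size unless ``pad=True``, in
    which case the image is reflect-padded on the bottom/right and the pad
    amounts are recorded in the partition so decryption can crop back.
    """
    if bx < 1 or by < 1:
        raise ValueError(f"block size must be positive, got ({bx}, {by})")
    px = img.pixels
    h, w = px.shape[:2]
    pad_bottom = (-h) % bx
    pad_right = (-w) % by
    if (pad_bottom or pad_right) and not pad:
        axis = "height" if pad_bottom else "width"
        raise ValueError(
            f"image {axis} ({h if pad_bottom else w}) is not divisible by the "
            f"block size ({bx if pad_bottom else by}); enable padding to proceed"
        )
    if pad_bottom or pad_right:
        widths = [(0, pad_bottom), (0, pad_right)] + [(0, 0)] * (px.ndim - 2)
        px = np.pad(px, widths, mode="reflect")
    n_rows = px.shape[0] // bx
    n_cols = px.shape[1] // by
    part = BlockPartition(bx, by, n_rows, n_cols, pad_bottom, pad_right)
    blocks = [
        px[r * bx : (r + 1) * bx, c * by : (c + 1) * by].copy()
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return part, blocks


def assemble_image(
    blocks: list[np.ndarray], part: BlockPartition, template: RasterImage
) -> RasterImage:
    """Reassemble row-major blocks into an image, cropping any padding."""
    sample = blocks[0]
    shape = (part.n_rows * part.bx, part.n_cols * part.by) + sample.shape[2:]
    out = np.empty(shape, dtype=sample.dtype)
    for idx, blk in enumerate(blocks):
        r, c = divmod(idx, part.n_cols)
        out[r * part.bx : (r + 1) * part.bx, c * part.by : (c + 1) * part.by] = blk
    if part.pad_bottom:
        out = out[: -part.pad_bottom]
    if part.pad_right:
        out = out[:, : -part.pad_right]
    return RasterImage(out, template.bit_depth, dict(template.metadata))


def negpos_transform(block: np.ndarray, r_i: int, bit_depth: int = 8) -> np.ndarray:
    """Negative-positive change: XOR every pixel with ``2**L - 1`` when r=1.

    Self-inverse (XOR involution); identity when ``r_i = 0``.  The same bit
    is applied to all colour components.
    """
    if r_i not in (0, 1):
        raise ValueError(f"r(i) must be a bit, got {r_i}")
    if r_i == 0:
        return block.copy()
    mask = (1 << bit_depth) - 1
    return (block.astype(np.int64) ^ mask).astype(block.dtype)


def dihedral_transform(block: np.ndarray, k2_i: int) -> np.ndarray:
    """Apply one of the 8 square symmetries: rot90 by ``k2_i % 4``, then a
    horizontal flip when ``k2_i >= 4``.  Index 0 is the identity."""
    if not 0 <= k2_i <= 7:
        raise ValueError(f"dihedral index must be in 0..7, got {k2_i}")
    if block.shape[0] != block.shape[1]:
        raise ValueError(f"dihedral transform needs a square block, got {block.shape[:2]}")
    out = np.rot90(block, k2_i % 4, axes=(0, 1))
    if k2_i >= 4:
        out = np.flip(out, axis=1)
    return out.copy()


def dihedral_inverse_index(k2_i: int) -> int:
    """Index whose transform undoes ``k2_i`` (rotations invert, reflections
    are involutions)."""
    if not 0 <= k2_i <= 7:
        raise ValueError(f"dihedral index must be in 0..7, got {k2_i}")
    return (4 - k2_i) % 4 if k2_i < 4 else k2_i


def shuffle_channels(block: np.ndarray, k4_i: int) -> np.ndarray:
    """Permute the three colour components by the ``k4_i``-th permutation."""
    if block.ndim != 3 or block.shape[2] != 3:
        raise ValueError("channel shuffle requires a 3-channel block")
    if not 0 <= k4_i <= 5:
        raise ValueError(f"channel permutation index must be in 0..5, got {k4_i}")
    return block[:, :, CHANNEL_PERMUTATIONS[k4_i]].copy()


def channel_inverse_index(k4_i: int) -> int:
    return _CHANNEL_INVERSE[k4_i]


def _check_key_sizes(keys: KeySet, part: BlockPartition) -> None:
    if keys.n_blocks != part.n_blocks:
        raise ValueError(
            f"key streams sized for {keys.n_blocks} blocks but partition has "
            f"{part.n_blocks}"
        )


def encrypt(
    img: RasterImage,
    keys: KeySet,
    part: BlockPartition | None = None,
    *,
    pad: bool = False,
    steps: tuple[bool, bool, bool, bool] = (True, True, True, True),
) -> RasterImage:
    """Encrypt an image blockwise: K1 scramble, K2 dihedral, K3 negative-
    positive, K4 channel shuffle, in that order.

    ``steps`` enables/disables (K1, K2, K3, K4) individually — useful for
    studying which steps preserve global pixel statistics.  K2/K3/K4 streams
    are indexed by the block's position *after* the K1 permutation.
    """
    if part is None:
        part, blocks = partition_image(img, 16, 16, pad=pad)
    else:
        _, blocks = partition_image(img, part.bx, part.by, pad=pad or bool(part.pad_bottom or part.pad_right))
    if part.bx != part.by and steps[1]:
        raise ValueError("dihedral step requires square blocks (Bx == By)")
    _check_key_sizes(keys, part)
    if steps[0]:
        blocks = [blocks[keys.k1[i]] for i in range(part.n_blocks)]
    out = []
    for i, blk in enumerate(blocks):
        if steps[1]:
            blk = dihedral_transform(blk, int(keys.k2[i]))
        if steps[2]:
            blk = negpos_transform(blk, int(keys.k3[i]), img.bit_depth)
        if steps[3] and blk.ndim == 3 and blk.shape[2] == 3:
            blk = shuffle_channels(blk, int(keys.k4[i]))
        out.append(blk)
    enc = assemble_image(out, BlockPartition(part.bx, part.by, part.n_rows, part.n_cols), img)
    enc.metadata["bsbe"] = {
        "block_size": [part.bx, part.by],
        "pad_bottom": part.pad_bottom,
        "pad_right": part.pad_right,
    }
    return enc


def decrypt(
    img: RasterImage,
    keys: KeySet,
    part: BlockPartition,
    *,
    steps: tuple[bool, bool, bool, bool] = (True, True, True, True),
) -> RasterImage:
    """Invert :func:`encrypt`: K4^-1, K3 (self-inverse), K2^-1, then K1^-1.

    ``part`` must carry the pad amounts recorded at encryption so the
    original dimensions can be restored.
    """
    _check_key_sizes(keys, part)
    # the ciphertext itself is exactly n_rows*bx x n_cols*by (never padded)
    _, blocks = partition_image(img, part.bx, part.by, pad=False)
    out = []
    for i, blk in enumerate(blocks):
        if steps[3] and blk.ndim == 3 and blk.shape[2] == 3:
            blk = shuffle_channels(blk, channel_inverse_index(int(keys.k4[i])))
        if steps[2]:
            blk = negpos_transform(blk, int(keys.k3[i]), img.bit_depth)
        if steps[1]:
            blk = dihedral_transform(blk, dihedral_inverse_index(int(keys.k2[i])))
        out.append(blk)
    if steps[0]:
        unscrambled: list[np.ndarray | None] = [None] * part.n_blocks
        for i in range(part.n_blocks):
            unscrambled[keys.k1[i]] = out[i]
        out = unscrambled  # type: ignore[assignment]
    return assemble_image(out, part, img)


def encrypt_image(
    img: RasterImage, master_seed: int, *, block_size: int = 16, pad: bool = False
) -> tuple[RasterImage, KeySet, BlockPartition]:
    """Convenience wrapper: partition, derive keys and encrypt in one call."""
    part, _ = partition_image(img, block_size, block_size, pad=pad)
    keys = derive_keys(master_seed, part.n_blocks)
    return encrypt(img, keys, part, pad=pad), keys, part


def decrypt_image(
    img: RasterImage,
    master_seed: int,
    *,
    block_size: int = 16,
    pad_bottom: int = 0,
    pad_right: int = 0,
) -> RasterImage:
    """Convenience wrapper mirroring :func:`encrypt_image`."""
    h, w = img.pixels.shape[:2]
    part = BlockPartition(
        block_size, block_size, h // block_size, w // block_size, pad_bottom, pad_right
    )
    keys = derive_keys(master_seed, part.n_blocks)
    return decrypt(img, keys, part)


def write_key_manifest(
    path: str | Path, *, master_seed: int, block_size: int, pad_bottom: int = 0, pad_right: int = 0
) -> Path:
    """Write a JSON key manifest (seed, block size, padding) for batch jobs.

    Keys are never embedded in image files; the manifest is the only
    key-bearing artifact and should be stored separately from ciphertexts.
    """
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "master_seed": master_seed,
                "block_size": block_size,
                "pad_bottom": pad_bottom,
                "pad_right": pad_right,
            },
            indent=2,
        )
    )
    return path


def read_key_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
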