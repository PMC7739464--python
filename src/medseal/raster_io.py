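"""8-bit grayscale raster I/O and the block-grid coordinate system.

Conventions used throughout the package: images are 2-D ``numpy.uint8``
arrays indexed ``[row, col]`` with row 0 at the top and column 0 at the
left (0-based, row-major). Tiles are half-open axis-aligned squares
``[row, row+size) x [col, col+size)``.

Only 8-bit grayscale PNG and PGM (P5, maxval 255) are accepted; color or
16-bit input is rejected rather than silently converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from PIL import Image

from .errors import FormatError

__all__ = [
    "Tile", "BlockGrid", "load_image", "save_image", "as_gray_image",
    "make_grid", "extract_block", "write_block",
]


class Tile(NamedTuple):
    """A square tile anchored at ``(row, col)`` with side ``size``."""

    row: int
    col: int
    size: int


def as_gray_image(pixels) -> np.ndarray:
    """Validate and return ``pixels`` as a 2-D uint8 array.

    Raises :class:`FormatError` for anything that is not a 2-D integer
    array with values in [0, 255].
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"expected a non-empty 2-D array, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"expected integer pixels, got dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError("pixel values outside [0, 255]")
    return arr.astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG or PGM file.

    Color, palette, and >8-bit images raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode != "L":
                raise FormatError(
                    f"{path.name}: mode {mode!r} is not 8-bit grayscale "
                    "(color or high-bit-depth input is rejected, not converted)"
                )
            arr = np.asarray(im, dtype=np.uint8)
    except FormatError:
        raise
    except Exception as exc:  # Pillow raises various classes for bad files
        raise FormatError(f"{path}: not a readable image ({exc})") from exc
    return as_gray_image(arr)


def save_image(image, path) -> None:
    """Write a grayscale image as PNG or PGM (by file extension), bit-exact."""
    arr = as_gray_image(image)
    path = Path(path)
    im = Image.fromarray(arr, mode="L")
    suffix = path.suffix.lower()
    if suffix in (".pgm", ".ppm", ".pnm"):
        im.save(path, format="PPM")  # Pillow writes binary P5 for mode L
    elif suffix == ".png":
        im.save(path, format="PNG")
    else:
        raise FormatError(f"unsupported output format {suffix!r} (use .png or .pgm)")


@dataclass(frozen=True)
class BlockGrid:
    """Maximal non-overlapping tiling of an image by ``block_size`` squares.

    Rows/columns that do not fill a whole tile are excluded from ``blocks``
    and recorded as ``residual`` (rows, cols) margin at bottom/right.
    """

    block_size: int
    origin: tuple[int, int]
    blocks: list[Tile] = field(repr=False)
    residual: tuple[int, int] = (0, 0)

    @property
    def shape(self) -> tuple[int, int]:
        """Grid dimensions as (tile rows, tile cols)."""
        rows = {t.row for t in self.blocks}
        cols = {t.col for t in self.blocks}
        return (len(rows), len(cols))


def make_grid(image, block_size: int, origin: tuple[int, int] = (0, 0)) -> BlockGrid:
    """Tile ``image`` with ``block_size`` squares anchored at ``origin``.

    A 512x512 image at block size 160 yields a 3x3 grid plus a 32-pixel
    residual margin on the right and bottom.
    """
    arr = as_gray_image(image)
    h, w = arr.shape
    r0, c0 = origin
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    if block_size > min(h - r0, w - c0):
        raise ValueError(
            f"block_size {block_size} exceeds usable image extent "
            f"{(h - r0, w - c0)}"
        )
    n_rows = (h - r0) // block_size
    n_cols = (w - c0) // block_size
    blocks = [
        Tile(r0 + i * block_size, c0 + j * block_size, block_size)
        for i in range(n_rows)
        for j in range(n_cols)
    ]
    residual = (h - r0 - n_rows * block_size, w - c0 - n_cols * block_size)
    return BlockGrid(block_size=block_size, origin=origin, blocks=blocks,
                     residual=residual)


def _check_tile(image: np.ndarray, tile: Tile) -> None:
    h, w = image.shape
    r, c, s = tile
    if r < 0 or c < 0 or s <= 0 or r + s > h or c + s > w:
        raise ValueError(f"tile {tile} out of bounds for image {image.shape}")


def extract_block(image, tile: Tile) -> np.ndarray:
    """Return a copy of the tile's pixels. In-bounds off-grid tiles are legal."""
    arr = as_gray_image(image)
    _check_tile(arr, tile)
    r, c, s = tile
    return arr[r:r + s, c:c + s].copy()


def write_block(image, tile: Tile, block) -> np.ndarray:
    """Return a new image with the tile replaced by ``block``."""
    arr = as_gray_image(image).copy()
    _check_tile(arr, tile)
    blk = as_gray_image(block)
    r, c, s = tile
    if blk.shape != (s, s):
        raise ValueError(f"block shape {blk.shape} does not match tile size {s}")
    arr[r:r + s, c:c + s] = blk
    return arr
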