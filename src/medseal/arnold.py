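"""Arnold cat-map scrambling of pixel positions within square blocks.

One step maps lattice point (x, y) to ((x + y) mod N, (x + 2y) mod N) --
the matrix [[1, 1], [1, 2]] acting modulo N. The map is a bijection on the
N x N lattice and is periodic: some iterate is the identity, with the
period depending on N. Scrambling a block k times is inverted either by
applying the inverse matrix [[2, -1], [-1, 1]] k times or by completing
the cycle with period(N) - k forward steps; both routes agree.

Coordinates follow the package convention: x is the row index, y the
column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .raster_io import Tile, as_gray_image

__all__ = [
    "ArnoldParams", "arnold_step", "arnold_inverse_step", "period",
    "scramble_block", "unscramble_block", "scramble_region",
    "unscramble_region", "DEFAULT_ITERATIONS",
]

DEFAULT_ITERATIONS = 4  # the worked parameter string "8 x 8 4"


@dataclass(frozen=True)
class ArnoldParams:
    """Block order N, iteration count k, and the tiles to scramble."""

    block_order: int = 8
    iterations: int = DEFAULT_ITERATIONS
    scramble_set: tuple[Tile, ...] = field(default=())

    def __post_init__(self):
        if self.block_order < 2:
            raise ValueError("block_order must be >= 2")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def arnold_step(x: int, y: int, n: int):
    """One forward cat-map step on the n x n lattice."""
    return (x + y) % n, (x + 2 * y) % n


def arnold_inverse_step(x: int, y: int, n: int):
    """One inverse step, via the inverse matrix [[2, -1], [-1, 1]] mod n."""
    return (2 * x - y) % n, (y - x) % n


@lru_cache(maxsize=None)
def period(n: int) -> int:
    """Smallest k >= 1 whose k-fold cat map is the identity on n x n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    xs0, ys0 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    xs, ys = (xs0 + ys0) % n, (xs0 + 2 * ys0) % n
    k = 1
    while not (np.array_equal(xs, xs0) and np.array_equal(ys, ys0)):
        xs, ys = (xs + ys) % n, (xs + 2 * ys) % n
        k += 1
    return k


@lru_cache(maxsize=None)
def _forward_permutation(n: int, k: int):
    """Index arrays (src_x, src_y) such that out = block[src_x, src_y].

    Built from the inverse map: the pixel landing at (x, y) after k
    forward steps originates at inverse^k (x, y).
    """
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    for _ in range(k % period(n)):
        xs, ys = (2 * xs - ys) % n, (ys - xs) % n
    return xs, ys


def scramble_block(block, k: int) -> np.ndarray:
    """Move the pixel at (x, y) to its k-step forward cat-map image."""
    arr = as_gray_image(block)
    n, m = arr.shape
    if n != m:
        raise ValueError(f"block must be square, got {arr.shape}")
    sx, sy = _forward_permutation(n, k)
    return arr[sx, sy]


def unscramble_block(block, k: int) -> np.ndarray:
    """Exact inverse of :func:`scramble_block` with the same k."""
    arr = as_gray_image(block)
    n, m = arr.shape
    if n != m:
        raise ValueError(f"block must be square, got {arr.shape}")
    return scramble_block(arr, period(n) - (k % period(n)))


def _apply(image, params: ArnoldParams, k_effective: int) -> np.ndarray:
    arr = as_gray_image(image).copy()
    n = params.block_order
    sx, sy = _forward_permutation(n, k_effective)
    for t in params.scramble_set:
        if t.size != n:
            raise ValueError(f"tile size {t.size} != block order {n}")
        blk = arr[t.row:t.row + n, t.col:t.col + n]
        arr[t.row:t.row + n, t.col:t.col + n] = blk[sx, sy]
    return arr


def scramble_region(image, params: ArnoldParams) -> np.ndarray:
    """Scramble every tile in ``params.scramble_set``; other pixels untouched."""
    return _apply(image, params, params.iterations % period(params.block_order))


def unscramble_region(image, params: ArnoldParams) -> np.ndarray:
    """Invert :func:`scramble_region` exactly."""
    p = period(params.block_order)
    return _apply(image, params, p - (params.iterations % p))
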