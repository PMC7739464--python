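"""Key-region detection and texture classification.

The sensitive "key region" is the 160x160 block with the largest
coefficient of variation C_v = sigma / mu, where sigma is the population
standard deviation sqrt((1/N) sum (x_i - mu)^2). C_v is a normalised
dispersion measure: lesions are texture-rich, so the block containing one
dominates the C_v ranking.

The rest of the image is split into 8x8 blocks whose mean squared
deviation from the block mean (equal to the block's population variance)
is compared against a threshold T: blocks with MSE > T form the texture
(embeddable) area, blocks with MSE <= T the smooth area. Blocks with
MSE > 0 form the scramble candidate set. Tiles overlapping the key region
are excluded from both the embeddable and scramble sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import Tile, as_gray_image, extract_block, make_grid

__all__ = [
    "KeyRegionStats", "TextureMap", "coefficient_of_variation",
    "select_key_region", "override_key_region", "block_mse",
    "classify_blocks", "tiles_to_mask", "mask_to_tiles",
    "KEY_REGION_SIZE", "TEXTURE_BLOCK_SIZE",
]

KEY_REGION_SIZE = 160
TEXTURE_BLOCK_SIZE = 8


@dataclass(frozen=True)
class KeyRegionStats:
    """Dispersion statistics of one key-region candidate block."""

    tile: Tile
    mu: float
    sigma: float
    cv: float
    n_pixels: int


def coefficient_of_variation(block, tile: Tile | None = None) -> KeyRegionStats:
    """Population mean/std and C_v = sigma/mu of a block.

    An all-black block (mu = 0) gets C_v = 0 by convention so that empty
    background can never win the key-region argmax.
    """
    arr = as_gray_image(block).astype(np.float64)
    mu = float(arr.mean())
    sigma = float(arr.std())  # population (1/N) form
    cv = sigma / mu if mu > 0 else 0.0
    if tile is None:
        tile = Tile(0, 0, arr.shape[0])
    return KeyRegionStats(tile=tile, mu=mu, sigma=sigma, cv=cv,
                          n_pixels=arr.size)


def select_key_region(image, block_size: int = KEY_REGION_SIZE) -> KeyRegionStats:
    """Pick the grid tile with maximal C_v (row-major first on ties)."""
    arr = as_gray_image(image)
    if min(arr.shape) < block_size:
        raise ValueError(
            f"image {arr.shape} admits no full {block_size}x{block_size} tile"
        )
    grid = make_grid(arr, block_size)
    best: KeyRegionStats | None = None
    for tile in grid.blocks:  # row-major order -> deterministic tie-break
        stats = coefficient_of_variation(extract_block(arr, tile), tile)
        if best is None or stats.cv > best.cv:
            best = stats
    assert best is not None
    return best


def override_key_region(image, tile: Tile) -> KeyRegionStats:
    """Statistics for a clinician-supplied key tile, bypassing the argmax.

    Off-grid (but in-bounds) placements are accepted.
    """
    arr = as_gray_image(image)
    return coefficient_of_variation(extract_block(arr, tile), tile)


def block_mse(block) -> float:
    """Mean squared deviation of a block from its own mean.

    With the reference taken as the block mean broadcast to every pixel,
    this equals the population variance (sigma^2 of
    :func:`coefficient_of_variation`).
    """
    arr = as_gray_image(block).astype(np.float64)
    return float(arr.var())


@dataclass(frozen=True)
class TextureMap:
    """Per-tile MSE classification of an image on the 8x8 grid.

    ``embeddable`` is sorted by ascending MSE (row-major tile index on
    ties); ``scramble_set`` keeps row-major order. Both exclude tiles
    overlapping the key region.
    """

    block_size: int
    mse: np.ndarray          # (tile_rows, tile_cols) float64
    threshold: float
    embeddable: tuple[Tile, ...]
    smooth: tuple[Tile, ...]
    scramble_set: tuple[Tile, ...]

    @property
    def embeddable_mask(self) -> np.ndarray:
        return tiles_to_mask(self.embeddable, self.mse.shape, self.block_size)

    @property
    def scramble_mask(self) -> np.ndarray:
        return tiles_to_mask(self.scramble_set, self.mse.shape, self.block_size)


def tiles_to_mask(tiles, grid_shape: tuple[int, int], block_size: int) -> np.ndarray:
    """Boolean (tile_rows, tile_cols) mask from a tile collection."""
    mask = np.zeros(grid_shape, dtype=bool)
    for t in tiles:
        mask[t.row // block_size, t.col // block_size] = True
    return mask


def mask_to_tiles(mask: np.ndarray, block_size: int) -> tuple[Tile, ...]:
    """Row-major tile list from a boolean tile mask."""
    rows, cols = np.nonzero(mask)
    return tuple(Tile(int(r) * block_size, int(c) * block_size, block_size)
                 for r, c in zip(rows, cols))


def _tile_variances(arr: np.ndarray, b: int) -> np.ndarray:
    h, w = arr.shape
    v = arr[: h - h % b, : w - w % b].astype(np.float64)
    tiles = v.reshape(h // b, b, w // b, b).transpose(0, 2, 1, 3)
    return tiles.reshape(h // b, w // b, b * b).var(axis=2)


def classify_blocks(image, threshold: float,
                    key_tile: Tile | None = None,
                    block_size: int = TEXTURE_BLOCK_SIZE) -> TextureMap:
    """Split the 8x8 grid into smooth/texture areas around the key region.

    The full image is tiled (512 is divisible by 8, so there is no
    residual on the canonical size). Tiles intersecting ``key_tile`` are
    excluded from the embeddable and scramble sets: that area is destined
    to hold the replacement code block, not hidden data.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    arr = as_gray_image(image)
    mse = _tile_variances(arr, block_size)

    overlap = np.zeros(mse.shape, dtype=bool)
    if key_tile is not None:
        kr, kc, ks = key_tile
        tr0 = kr // block_size
        tc0 = kc // block_size
        tr1 = (kr + ks - 1) // block_size
        tc1 = (kc + ks - 1) // block_size
        overlap[max(tr0, 0):tr1 + 1, max(tc0, 0):tc1 + 1] = True

    emb_mask = (mse > threshold) & ~overlap
    smooth_mask = mse <= threshold
    scr_mask = (mse > 0) & ~overlap

    emb_idx = np.argwhere(emb_mask)
    # ascending MSE, ties broken by row-major tile index
    order = np.lexsort((emb_idx[:, 1], emb_idx[:, 0],
                        mse[emb_idx[:, 0], emb_idx[:, 1]]))
    embeddable = tuple(
        Tile(int(r) * block_size, int(c) * block_size, block_size)
        for r, c in emb_idx[order]
    )
    return TextureMap(
        block_size=block_size,
        mse=mse,
        threshold=float(threshold),
        embeddable=embeddable,
        smooth=mask_to_tiles(smooth_mask, block_size),
        scramble_set=mask_to_tiles(scr_mask, block_size),
    )
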