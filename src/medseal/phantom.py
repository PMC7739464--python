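"""Seeded generator of synthetic medical-style test images.

Real evaluation data for this kind of pipeline are curated CT slices:
texture-rich, organ filling most of the frame, with a well-localised
lesion. The phantom emulates exactly those selection criteria so every
pipeline stage is exercisable without downloads:

* a dark, nearly smooth background in the frame corners;
* a bright quasi-circular "organ" occupying the great majority of the
  image, carrying band-limited texture (white noise smoothed by a 3x3
  mean filter, as CT noise is) strong enough that its 8x8 blocks are
  texture-classified at every threshold in the 5..50 sweep family;
* a rectangular band of tiles whose texture amplitude tapers so their
  block MSEs spread over a configurable range -- these are the blocks a
  threshold sweep progressively drops, with a deliberate MSE gap above
  the band so the sweep's quality curve visibly plateaus;
* a high-contrast bimodal lesion patch filling one 160-grid tile, whose
  coefficient of variation dominates every other tile by construction.

Generation is deterministic per seed. After synthesis the generator
verifies the two invariants the pipeline relies on -- C_v dominance of
the lesion tile and embedding capacity for the full 204,800-bit
key-region stream within the [-2,2]..[-20,20] range family -- and
regenerates with boosted contrast/texture if either fails.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter

from . import rdh_pee, region_select
from .errors import GenerationError
from .raster_io import Tile
from .region_select import KEY_REGION_SIZE, TEXTURE_BLOCK_SIZE

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite"]

_KEY_STREAM_BITS = KEY_REGION_SIZE * KEY_REGION_SIZE * 8  # 204,800


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic image.

    ``lesion_tile`` is a position on the 160-grid in tile units (row,
    col); ``band_tiles`` is (tile_row0, tile_col0, n_rows, n_cols) on the
    8x8 grid; MSE values are in squared gray levels.
    """

    seed: int = 0
    size: int = 512
    organ_radius_frac: float = 0.684
    organ_base: float = 100.0
    organ_contrast: float = 30.0
    core_mse: float = 300.0
    band_mse: tuple[float, float] = (8.0, 40.0)
    band_tiles: tuple[int, int, int, int] = (56, 6, 4, 50)
    lesion_tile: tuple[int, int] = (1, 1)
    lesion_contrast: float = 70.0
    background_level: float = 40.0
    background_texture: float = 1.0

    @property
    def lesion_pixel_tile(self) -> Tile:
        r, c = self.lesion_tile
        return Tile(r * KEY_REGION_SIZE, c * KEY_REGION_SIZE, KEY_REGION_SIZE)


def _synthesize(spec: PhantomSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    b = TEXTURE_BLOCK_SIZE
    ctr = (s - 1) / 2.0
    radius = spec.organ_radius_frac * s
    rr, cc = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
    rad = np.hypot(rr - ctr, cc - ctr)

    # smooth organ/background intensity blend: a hard edge would hand
    # boundary tiles arbitrary MSE values, muddying texture classification
    ramp = 4 * b
    blend = np.clip((radius - rad) / ramp, 0.0, 1.0)
    profile = spec.organ_base + spec.organ_contrast * (1.0 - (rad / radius) ** 2)
    base = spec.background_level + (profile - spec.background_level) * blend

    # band-limited unit-variance texture field
    field = uniform_filter(rng.standard_normal((s, s)), 3)
    field /= field.std()

    # core texture amplitude only on tiles wholly inside the organ, so
    # every 8x8 tile is either textured or background -- never a mix
    core_px = rad <= radius - ramp
    tile_core = core_px.reshape(s // b, b, s // b, b).all(axis=(1, 3))
    amp = np.where(np.repeat(np.repeat(tile_core, b, 0), b, 1),
                   np.sqrt(spec.core_mse), spec.background_texture)

    img = base + amp * field

    # band tiles: texture renormalised per tile to hit the target MSE
    # exactly, so the band's upper edge cannot stray into the MSE gap the
    # threshold-sweep plateau relies on
    tr0, tc0, nr, nc = spec.band_tiles
    targets = np.linspace(spec.band_mse[0], spec.band_mse[1], nr * nc)
    i = 0
    for tr in range(tr0, tr0 + nr):
        for tc in range(tc0, tc0 + nc):
            sl = (slice(tr * b, (tr + 1) * b), slice(tc * b, (tc + 1) * b))
            ft = field[sl]
            ft = (ft - ft.mean()) / ft.std()
            img[sl] = base[sl] + np.sqrt(targets[i]) * ft
            i += 1

    lt = spec.lesion_pixel_tile
    n = lt.size
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    lesion = 127.0 + spec.lesion_contrast * signs + rng.normal(0, 5.0, (n, n))
    img[lt.row:lt.row + n, lt.col:lt.col + n] = lesion

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _check_invariants(img: np.ndarray, spec: PhantomSpec) -> bool:
    lt = spec.lesion_pixel_tile
    chosen = region_select.select_key_region(img)
    if (chosen.tile.row, chosen.tile.col) != (lt.row, lt.col):
        return False
    tmap = region_select.classify_blocks(img, 5.0, key_tile=lt)
    params = rdh_pee.PEEParams(p=-20, q=20)
    cap = rdh_pee.capacity(img, tmap, params, key_tile=lt)
    return cap >= _KEY_STREAM_BITS


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic lesion-bearing test image for a spec.

    Raises :class:`GenerationError` for unsatisfiable specs (e.g. zero
    lesion contrast, which cannot dominate the C_v ranking).
    """
    s = spec.size
    if s < KEY_REGION_SIZE:
        raise GenerationError(f"size {s} cannot hold a key region")
    r, c = spec.lesion_tile
    if not (0 <= r < s // KEY_REGION_SIZE and 0 <= c < s // KEY_REGION_SIZE):
        raise GenerationError(f"lesion tile {spec.lesion_tile} off the "
                              "160-grid")
    if spec.lesion_contrast <= 0:
        raise GenerationError("a zero-contrast lesion cannot dominate the "
                              "C_v ranking")
    attempt = spec
    for _ in range(4):
        img = _synthesize(attempt)
        if _check_invariants(img, attempt):
            return img
        # boost the discriminating features and retry
        attempt = replace(attempt,
                          lesion_contrast=attempt.lesion_contrast * 1.4 + 10,
                          core_mse=attempt.core_mse * 1.2)
        if attempt.lesion_contrast > 500:
            break
    raise GenerationError(
        f"spec (seed={spec.seed}) cannot satisfy the C_v-dominance and "
        "capacity invariants")


def generate_suite(n: int, base_seed: int = 0) -> list[np.ndarray]:
    """``n`` phantoms with varied lesion positions and contrasts.

    Seeds run ``base_seed .. base_seed + n - 1``; lesion tiles cycle over
    the nine 160-grid positions of a 512 image.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positions = [(i, j) for i in range(3) for j in range(3)]
    out = []
    for i in range(n):
        if i == 0:
            spec = PhantomSpec(seed=base_seed)
        else:
            spec = PhantomSpec(
                seed=base_seed + i,
                lesion_tile=positions[i % len(positions)],
                lesion_contrast=60.0 + 5.0 * (i % 4),
            )
        out.append(generate_phantom(spec))
    return out
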