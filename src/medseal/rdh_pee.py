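"""Reversible data hiding by prediction-error expansion (PEE).

Each target pixel v is predicted as the mean u of its four horizontal and
vertical neighbours (the diamond predictor); the prediction error is
d = floor(u - v). Errors inside a selection range [p, q] are expanded to
D = 2d + b to carry one payload bit b; errors outside the range are
shifted out of the way by a constant (d + q + 1 above, d + p below) so
that expanded and shifted errors never collide -- the histogram-shifting
step. The stego pixel is v' = v + (d - D), the unique integer for which
floor(u - v') = D, so decoding recovers D exactly and inverts every step:
b = D mod 2 and d = floor(D / 2) inside [2p, 2q+1], d = D - q - 1 above,
d = D + |p| below, then v = v' + (D - d).

Embedding runs in two checkerboard passes over the eligible pixels of the
embeddable tiles: first all (row + col) even pixels, then all odd ones.
A pixel's four predictors always have the opposite parity, so the
predictors of pass-1 targets are untouched during pass 1, and pass-2
predictors -- although modified by pass 1 -- are stable during pass 2.
Extraction replays the passes in reverse (odd first), seeing each
predictor in exactly the state it had at embedding time. Prediction may
cross tile boundaries: eligible pixels only need their four neighbours
inside the image and outside the (one-pixel-dilated) key region, whose
content is replaced downstream and hence unavailable at extraction time.

Pixels whose modified value would leave [0, 255] are skipped and recorded
in a location map carried as side-information; within each pass, payload
bits fill the carrier pixels in row-major order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, IntegrityError
from .raster_io import Tile, as_gray_image
from .region_select import TextureMap

__all__ = [
    "PEEParams", "PEERecord", "predict", "map_error", "unmap_error",
    "embed_stream", "extract_stream", "capacity",
    "bytes_to_bits", "bits_to_bytes", "block_to_bits", "bits_to_block",
    "RANGE_FAMILY",
]

#: symmetric error-range family widened through on capacity shortfall
RANGE_FAMILY: tuple[tuple[int, int], ...] = tuple(
    (-m, m) for m in range(2, 21)
)


@dataclass(frozen=True)
class PEEParams:
    """Error selection range [p, q] and the layer (parity) order."""

    p: int = -2
    q: int = 2
    layer_order: str = "even"  # parity of (row + col) embedded first
    block_scan: tuple[Tile, ...] | None = None

    def __post_init__(self):
        if not (self.p <= 0 <= self.q):
            raise ValueError(f"need p <= 0 <= q, got [{self.p}, {self.q}]")
        if self.layer_order not in ("even", "odd"):
            raise ValueError("layer_order must be 'even' or 'odd'")


@dataclass(frozen=True)
class PEERecord:
    """Side-information produced by embedding, required for extraction."""

    params: PEEParams
    payload_bits: int
    location_map: tuple[tuple[int, int], ...] = field(default=(), repr=False)
    layers_used: int = 2


# ---------------------------------------------------------------- scalars

def predict(image, x: int, y: int):
    """Diamond prediction at (x, y): returns (u, d) or None on the border.

    u is the four-neighbour mean, d = floor(u - v) with floor toward -inf.
    Border pixels (missing a neighbour) are simply not embedding targets,
    signalled by ``None`` rather than an exception.
    """
    arr = as_gray_image(image).astype(np.int64)
    h, w = arr.shape
    if not (0 < x < h - 1 and 0 < y < w - 1):
        return None
    s = int(arr[x, y - 1] + arr[x, y + 1] + arr[x - 1, y] + arr[x + 1, y])
    u = s / 4.0
    d = (s - 4 * int(arr[x, y])) >> 2  # floor((u - v)) exactly, integers
    return u, d


def map_error(d: int, b: int | None, params: PEEParams) -> int:
    """Three-case expansion/shift of a prediction error."""
    p, q = params.p, params.q
    if p <= d <= q:
        if b not in (0, 1):
            raise ValueError("bit must be 0 or 1 for in-range errors")
        return 2 * d + b
    if d > q:
        return d + q + 1
    return d + p


def unmap_error(D: int, params: PEEParams):
    """Exact inverse of :func:`map_error`: returns (d, bit-or-None)."""
    p, q = params.p, params.q
    if 2 * p <= D <= 2 * q + 1:
        return math.floor(D / 2), D % 2  # python % is the mathematical mod
    if D > 2 * q + 1:
        return D - q - 1, None
    return D - p, None


# ------------------------------------------------------------- bit plumbing

def bytes_to_bits(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bits_to_bytes(bits: np.ndarray) -> bytes:
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size % 8:
        raise ValueError("bit count must be a multiple of 8")
    return np.packbits(bits).tobytes()


def block_to_bits(block) -> np.ndarray:
    """Row-major, MSB-first bitstream of a pixel block (8 bits per pixel)."""
    arr = as_gray_image(block)
    return np.unpackbits(arr.reshape(-1))


def bits_to_block(bits: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`block_to_bits`."""
    n = shape[0] * shape[1] * 8
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size != n:
        raise ValueError(f"need {n} bits for shape {shape}, got {bits.size}")
    return np.packbits(bits).reshape(shape)


# ------------------------------------------------------------- pixel masks

def _eligible_mask(shape: tuple[int, int], texture_map: TextureMap,
                   key_tile: Tile | None) -> np.ndarray:
    """Pixels of embeddable tiles with a full in-image diamond that does
    not reach into the (dilated) key region."""
    h, w = shape
    b = texture_map.block_size
    tile_mask = texture_map.embeddable_mask
    pix = np.zeros(shape, dtype=bool)
    th, tw = tile_mask.shape
    pix[:th * b, :tw * b] = np.repeat(np.repeat(tile_mask, b, axis=0), b, axis=1)
    pix[0, :] = pix[-1, :] = False
    pix[:, 0] = pix[:, -1] = False
    if key_tile is not None:
        kr, kc, ks = key_tile
        pix[max(kr - 1, 0):kr + ks + 1, max(kc - 1, 0):kc + ks + 1] = False
    return pix


def _neighbour_sum(work: np.ndarray) -> np.ndarray:
    s = np.zeros_like(work)
    s[1:-1, 1:-1] = (work[:-2, 1:-1] + work[2:, 1:-1]
                     + work[1:-1, :-2] + work[1:-1, 2:])
    return s


def _parity_grid(shape: tuple[int, int]) -> np.ndarray:
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return (r + c) % 2


# ---------------------------------------------------------------- embedding

def _encode_pass(work: np.ndarray, elig: np.ndarray, p: int, q: int,
                 bits: np.ndarray, offset: int):
    """One checkerboard embedding pass, in place on ``work`` (int32).

    Returns (bits consumed, overflow coordinate list).
    """
    d = (_neighbour_sum(work) - 4 * work) // 4
    v = work
    inr = elig & (d >= p) & (d <= q)
    hi = elig & (d > q)
    lo = elig & (d < p)
    over = ((inr & ((v - d - 1 < 0) | (v - d > 255)))
            | (hi & (v - (q + 1) < 0))
            | (lo & (v - p > 255)))
    carriers = inr & ~over
    rows, cols = np.nonzero(carriers)          # row-major carrier order
    n = rows.size
    chunk = np.zeros(n, dtype=np.int32)
    avail = bits[offset:offset + n]
    chunk[:avail.size] = avail                 # zero-pad past the payload
    work[rows, cols] = v[rows, cols] - d[rows, cols] - chunk
    work[hi & ~over] -= q + 1
    work[lo & ~over] -= p
    orr, occ = np.nonzero(over)
    return n, list(zip(orr.tolist(), occ.tolist()))


def embed_stream(image, texture_map: TextureMap, stream,
                 params: PEEParams = PEEParams(),
                 key_tile: Tile | None = None):
    """Embed a bitstream into the texture area; returns (stego, record).

    Every eligible pixel of every embeddable tile is processed: in-range
    errors are expanded (payload zero-padded up to capacity), out-of-range
    errors histogram-shifted, would-overflow pixels skipped into the
    location map. Raises :class:`CapacityError` if the stream does not fit.
    """
    arr = as_gray_image(image)
    bits = np.asarray(stream, dtype=np.uint8).ravel()
    if bits.size and not np.all((bits == 0) | (bits == 1)):
        raise ValueError("stream must contain only 0/1 bits")
    work = arr.astype(np.int32)
    elig = _eligible_mask(arr.shape, texture_map, key_tile)
    par = _parity_grid(arr.shape)
    first = 0 if params.layer_order == "even" else 1

    n1, over1 = _encode_pass(work, elig & (par == first),
                             params.p, params.q, bits, 0)
    n2, over2 = _encode_pass(work, elig & (par == 1 - first),
                             params.p, params.q, bits, n1)
    total = n1 + n2
    if total < bits.size:
        raise CapacityError(
            f"payload needs {bits.size} bits but only {total} carrier "
            f"pixels exist at range [{params.p}, {params.q}]",
            required=bits.size, available=total)
    record = PEERecord(params=params, payload_bits=int(bits.size),
                       location_map=tuple(over1 + over2), layers_used=2)
    return work.astype(np.uint8), record


# --------------------------------------------------------------- extraction

def _decode_pass(work: np.ndarray, elig: np.ndarray, p: int, q: int):
    """One checkerboard restoration pass, in place; returns the pass bits."""
    D = (_neighbour_sum(work) - 4 * work) // 4
    emb = elig & (D >= 2 * p) & (D <= 2 * q + 1)
    hi = elig & (D > 2 * q + 1)
    lo = elig & (D < 2 * p)
    rows, cols = np.nonzero(emb)
    Dc = D[rows, cols]
    d = Dc // 2
    bits = (Dc - 2 * d).astype(np.uint8)
    work[rows, cols] += Dc - d                  # v = v' + (D - d)
    work[hi] += q + 1
    work[lo] += p
    return bits


def extract_stream(stego, record: PEERecord, texture_map: TextureMap,
                   key_tile: Tile | None = None, strict: bool = True):
    """Recover the embedded bits and the bit-exact original pixels.

    Replays the embedding passes in reverse parity order. With
    ``strict=True`` an image/record mismatch (fewer carriers than
    ``payload_bits``) raises :class:`IntegrityError`; with
    ``strict=False`` whatever bits exist are returned (used to
    demonstrate what a forced, keyless extraction yields).
    """
    arr = as_gray_image(stego)
    work = arr.astype(np.int32)
    params = record.params
    elig = _eligible_mask(arr.shape, texture_map, key_tile)
    for r, c in record.location_map:
        elig[r, c] = False
    par = _parity_grid(arr.shape)
    first = 0 if params.layer_order == "even" else 1

    bits_second = _decode_pass(work, elig & (par == 1 - first),
                               params.p, params.q)
    bits_first = _decode_pass(work, elig & (par == first),
                              params.p, params.q)
    stream = np.concatenate([bits_first, bits_second])
    if stream.size < record.payload_bits:
        if strict:
            raise IntegrityError(
                f"record promises {record.payload_bits} bits but the image "
                f"yields only {stream.size}")
    restored = np.clip(work, 0, 255).astype(np.uint8)
    return stream[:record.payload_bits], restored


# ----------------------------------------------------------------- capacity

def capacity(image, texture_map: TextureMap,
             params: PEEParams = PEEParams(),
             key_tile: Tile | None = None) -> int:
    """Carrier-pixel count measured on the unmodified image.

    Counts eligible pixels whose prediction error (from original
    neighbours) lies in [p, q] and whose expansion cannot overflow. The
    realised two-pass capacity can differ by a handful of pixels because
    first-pass writes perturb second-pass predictions;
    :func:`embed_stream` is authoritative and raises on shortfall.
    """
    arr = as_gray_image(image)
    work = arr.astype(np.int32)
    d = (_neighbour_sum(work) - 4 * work) // 4
    elig = _eligible_mask(arr.shape, texture_map, key_tile)
    inr = elig & (d >= params.p) & (d <= params.q)
    ok = inr & (work - d - 1 >= 0) & (work - d <= 255)
    return int(ok.sum())
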