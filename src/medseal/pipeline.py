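"""End-to-end encryption/decryption pipeline and quality metrics.

Encryption: select the 160x160 key region by maximal coefficient of
variation -> serialise its 25,600 pixels into a 204,800-bit stream ->
classify 8x8 blocks into smooth/texture areas at threshold T -> embed the
stream into the texture area by prediction-error expansion (widening the
error range through [-2,2] ... [-20,20] until it fits) -> Arnold-scramble
the embedded blocks -> replace the key region with a code block carrying
cleartext metadata and the RSA-encrypted inversion parameters.

Decryption inverts each stage in reverse and reproduces the original
image bit-exactly; every parameter it needs travels inside the code
block, so possession of the private key is the only requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from random import Random

import numpy as np
from scipy.ndimage import uniform_filter

from . import arnold, qr_payload, rdh_pee, region_select
from .errors import CapacityError
from .qr_payload import (BasicInfo, ProtectedParams, QRPayload,
                         RSAPrivateKey, RSAPublicKey)
from .raster_io import Tile, as_gray_image, extract_block, write_block
from .region_select import KEY_REGION_SIZE, TEXTURE_BLOCK_SIZE, TextureMap

logger = logging.getLogger("medseal")

__all__ = [
    "EncryptionResult", "QualityReport", "encrypt", "decrypt",
    "inspect_qr", "unauthorized_key_region", "psnr", "ssim",
    "threshold_sweep", "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 5.0


@dataclass(frozen=True)
class EncryptionResult:
    """Encrypted image plus the encryptor-side audit trail.

    ``protected`` duplicates what travels encrypted inside the code block;
    it is sensitive and exists so the encrypting party can audit or
    archive its own run, never something to ship with the image.
    """

    encrypted_image: np.ndarray = field(repr=False)
    qr_tile: Tile
    config_echo: dict
    protected: ProtectedParams = field(repr=False)
    payload: QRPayload = field(repr=False)


@dataclass(frozen=True)
class QualityReport:
    psnr: float
    ssim: float


def _range_schedule(error_range: tuple[int, int]):
    p0, q0 = error_range
    if not (p0 <= 0 <= q0):
        raise ValueError(f"invalid error range {error_range}")
    wider = [r for r in rdh_pee.RANGE_FAMILY if r[1] > q0 or r[0] < p0]
    return [(p0, q0)] + wider


def encrypt(image, basic_info: BasicInfo, public_key: RSAPublicKey,
            threshold: float = DEFAULT_THRESHOLD,
            error_range: tuple[int, int] = (-2, 2),
            arnold_k: int = arnold.DEFAULT_ITERATIONS,
            key_tile: Tile | None = None,
            rng: Random | int | None = None) -> EncryptionResult:
    """Run the full five-stage protection of a grayscale image.

    ``key_tile`` overrides the automatic key-region choice (clinician
    calibration); ``rng`` seeds the session-key/nonce material so runs can
    be made reproducible. The image path itself is deterministic.
    """
    arr = as_gray_image(image)
    if min(arr.shape) < KEY_REGION_SIZE:
        raise ValueError(
            f"image {arr.shape} is smaller than the {KEY_REGION_SIZE}x"
            f"{KEY_REGION_SIZE} key region")
    if isinstance(rng, int):
        rng = Random(rng)

    if key_tile is None:
        stats = region_select.select_key_region(arr)
    else:
        stats = region_select.override_key_region(arr, key_tile)
    ktile = stats.tile
    logger.info("key region at %s (cv=%.4f)", (ktile.row, ktile.col), stats.cv)

    key_block = extract_block(arr, ktile)
    stream = rdh_pee.block_to_bits(key_block)

    tmap = region_select.classify_blocks(arr, threshold, key_tile=ktile)
    logger.info("threshold %.2f: %d embeddable / %d scramble-candidate tiles",
                threshold, len(tmap.embeddable), len(tmap.scramble_set))

    stego = record = None
    last_short: CapacityError | None = None
    for p, q in _range_schedule(error_range):
        params = rdh_pee.PEEParams(p=p, q=q)
        est = rdh_pee.capacity(arr, tmap, params, key_tile=ktile)
        if est + 256 < stream.size:      # clearly short; skip the dry run
            last_short = CapacityError("estimate short", required=stream.size,
                                       available=est)
            continue
        try:
            stego, record = rdh_pee.embed_stream(arr, tmap, stream, params,
                                                 key_tile=ktile)
            break
        except CapacityError as exc:
            last_short = exc
    if stego is None or record is None:
        raise CapacityError(
            f"key-region stream of {stream.size} bits does not fit even at "
            f"range [-20, 20]; largest capacity seen was "
            f"{last_short.available if last_short else 0} bits",
            required=stream.size,
            available=last_short.available if last_short else 0)
    logger.info("embedded %d bits at range [%d, %d], %d overflow pixels",
                record.payload_bits, record.params.p, record.params.q,
                len(record.location_map))

    aparams = arnold.ArnoldParams(block_order=TEXTURE_BLOCK_SIZE,
                                  iterations=arnold_k,
                                  scramble_set=tmap.embeddable)
    scrambled = arnold.scramble_region(stego, aparams)

    protected = ProtectedParams(
        arnold_text=qr_payload.format_arnold_text(TEXTURE_BLOCK_SIZE, arnold_k),
        key_tile=ktile,
        pee_record=record,
        embeddable_mask=tmap.embeddable_mask,
        scramble_mask=tmap.embeddable_mask.copy(),
        image_shape=arr.shape,
        block_size=TEXTURE_BLOCK_SIZE,
    )
    ciphertext = qr_payload.encrypt_params(protected, public_key, rng=rng)
    payload = QRPayload(basic=basic_info, ciphertext=ciphertext)
    qr_block = qr_payload.render_qr(payload)
    encrypted = write_block(scrambled, ktile, qr_block)

    echo = {"threshold": float(threshold),
            "range": (record.params.p, record.params.q),
            "arnold_k": int(arnold_k),
            "payload_bits": record.payload_bits,
            "embeddable_tiles": len(tmap.embeddable),
            "overflow_pixels": len(record.location_map)}
    logger.info("encrypted image ready: %s", echo)
    return EncryptionResult(encrypted_image=encrypted, qr_tile=ktile,
                            config_echo=echo, protected=protected,
                            payload=payload)


def _texture_map_from_masks(protected: ProtectedParams) -> TextureMap:
    """Decoder-side stand-in for the encoder's TextureMap: the carried
    masks are authoritative, the MSE grid and threshold are not needed."""
    b = protected.block_size
    emb = protected.embeddable_mask
    return TextureMap(
        block_size=b,
        mse=np.zeros(emb.shape),
        threshold=0.0,
        embeddable=region_select.mask_to_tiles(emb, b),
        smooth=(),
        scramble_set=region_select.mask_to_tiles(protected.scramble_mask, b),
    )


def decrypt(encrypted, private_key: RSAPrivateKey) -> np.ndarray:
    """Invert :func:`encrypt` and return the bit-exact original image.

    A wrong key fails authentication before any image processing; a
    tampered or missing code block raises :class:`QRDecodeError`.
    """
    arr = as_gray_image(encrypted)
    tile, payload = qr_payload.locate_qr(arr)
    protected = qr_payload.decrypt_params(payload.ciphertext, private_key)
    order, k = qr_payload.parse_arnold_text(protected.arnold_text)
    tmap = _texture_map_from_masks(protected)
    ktile = protected.key_tile
    logger.info("code block at %s; inverting %d Arnold steps on %d tiles",
                (tile.row, tile.col), k, len(tmap.scramble_set))

    aparams = arnold.ArnoldParams(block_order=order, iterations=k,
                                  scramble_set=tmap.scramble_set)
    unscrambled = arnold.unscramble_region(arr, aparams)

    bits, restored = rdh_pee.extract_stream(unscrambled, protected.pee_record,
                                            tmap, key_tile=ktile)
    key_block = rdh_pee.bits_to_block(bits, (ktile.size, ktile.size))
    return write_block(restored, ktile, key_block)


def inspect_qr(encrypted) -> tuple[Tile, BasicInfo]:
    """Read the cleartext metadata without any key material."""
    tile, payload = qr_payload.locate_qr(as_gray_image(encrypted))
    return tile, payload.basic


def unauthorized_key_region(encrypted, protected: ProtectedParams) -> np.ndarray:
    """What a keyless adversary reconstructs by brute force.

    Models the strongest unauthorized attempt: the adversary knows the
    algorithm and even the embedding geometry, but cannot decrypt the
    descrambling parameters, so the bitstream is read straight off the
    still-scrambled texture blocks. The result is reassembled into a
    160x160 block for comparison against the true key region.
    """
    arr = as_gray_image(encrypted)
    tmap = _texture_map_from_masks(protected)
    rec = protected.pee_record
    bits, _ = rdh_pee.extract_stream(arr, rec, tmap,
                                     key_tile=protected.key_tile,
                                     strict=False)
    full = np.zeros(rec.payload_bits, dtype=np.uint8)
    full[:bits.size] = bits[:rec.payload_bits]
    size = protected.key_tile.size
    return rdh_pee.bits_to_block(full, (size, size))


# ---------------------------------------------------------------- metrics

def psnr(a, b) -> float:
    """Peak signal-to-noise ratio in dB over all pixels, MAX = 255.

    Returns ``inf`` for identical images (the lossless certificate).
    """
    x = as_gray_image(a).astype(np.float64)
    y = as_gray_image(b).astype(np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0:
        return float("inf")
    return float(10 * np.log10(255.0 ** 2 / mse))


def ssim(a, b, win: int = 8, L: float = 255.0,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with a uniform ``win`` x ``win`` window.

    Standard stabilising constants C1 = (k1 L)^2, C2 = (k2 L)^2; the
    window defaults to 8 to match the texture block size. Identical
    images score exactly 1.
    """
    x = as_gray_image(a).astype(np.float64)
    y = as_gray_image(b).astype(np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    mu_x = uniform_filter(x, win)
    mu_y = uniform_filter(y, win)
    sxx = uniform_filter(x * x, win) - mu_x ** 2
    syy = uniform_filter(y * y, win) - mu_y ** 2
    sxy = uniform_filter(x * y, win) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def threshold_sweep(image, thresholds, basic_info: BasicInfo,
                    public_key: RSAPublicKey, seed: int = 0,
                    **encrypt_kwargs) -> list[QualityReport]:
    """Encrypt at each threshold and report encrypted-vs-original quality.

    The error selection range is chosen once -- wide enough for the
    smallest texture area in the sweep (the largest threshold) -- and
    held fixed, so per-pixel embedding distortion is comparable across
    thresholds and the quality curve isolates the effect of T, as when
    sweeping a fixed-range embedder. The session material is re-seeded
    identically per threshold so two thresholds selecting the same
    texture area produce the same encrypted image -- the quality curve
    then plateaus exactly once the threshold passes the last block-MSE
    value it can cross.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    arr = as_gray_image(image)

    if "error_range" not in encrypt_kwargs:
        ktile = encrypt_kwargs.get("key_tile")
        stats = (region_select.select_key_region(arr) if ktile is None
                 else region_select.override_key_region(arr, ktile))
        tmap = region_select.classify_blocks(arr, thresholds[-1],
                                             key_tile=stats.tile)
        need = stats.tile.size ** 2 * 8
        for p, q in _range_schedule((-2, 2)):
            est = rdh_pee.capacity(arr, tmap, rdh_pee.PEEParams(p=p, q=q),
                                   key_tile=stats.tile)
            if est >= need + 1024:
                encrypt_kwargs = {**encrypt_kwargs, "error_range": (p, q)}
                break

    reports = []
    for t in thresholds:
        res = encrypt(arr, basic_info, public_key, threshold=t,
                      rng=Random(seed), **encrypt_kwargs)
        reports.append(QualityReport(psnr=psnr(arr, res.encrypted_image),
                                     ssim=ssim(arr, res.encrypted_image)))
    return reports
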