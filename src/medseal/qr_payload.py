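"""The 160x160 code block that replaces the key region.

The block carries two payload sections, mirroring how the protected image
is meant to be used in the clinic:

* cleartext **basic information** about the image (hospital, department,
  doctor number, patient number, shooting time, contact number, image
  type), readable by anyone who scans the block; and
* a **ciphertext** section holding every parameter needed to invert the
  protection -- the Arnold parameter string (e.g. ``"8 × 8 4"``), the key
  tile, the embedding record, and the texture/scramble tile masks --
  recoverable only with the matching RSA private key.

Encryption is hybrid: a fresh 256-bit session key is wrapped with
RSA-OAEP (SHA-256) and the serialized parameters are encrypted with a
SHA-256 counter-mode keystream and authenticated encrypt-then-MAC with
HMAC-SHA256. Plain textbook RSA could not hold the side-information the
lossless contract needs, and unauthenticated decryption with a wrong key
would emit garbage instead of failing cleanly.

The symbol itself is a compact synthetic 2-D matrix barcode designed for
this package (quiet zone, two finder squares, a striped sync band, and a
CRC-32-framed bit area at one pixel per module). It is *not* an
ISO/IEC 18004 QR symbol and general-purpose QR readers will not decode
it; within the pipeline it plays exactly the QR code's role: 25,600
binarized pixels replacing the key region, machine-decodable when intact
and failing loudly when tampered with or scrambled.
"""

from __future__ import annotations

import base64
import hashlib
import hmac as hmac_mod
import json
import secrets
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from random import Random

import numpy as np
from sympy import isprime

from .errors import CapacityError, KeyAuthError, QRDecodeError
from .raster_io import Tile, as_gray_image
from .rdh_pee import PEEParams, PEERecord

__all__ = [
    "BasicInfo", "ProtectedParams", "QRPayload",
    "RSAPublicKey", "RSAPrivateKey", "generate_keypair",
    "save_key", "load_public_key", "load_private_key",
    "encrypt_params", "decrypt_params",
    "render_qr", "decode_qr", "locate_qr",
    "format_arnold_text", "parse_arnold_text",
    "QR_SIZE",
]

QR_SIZE = 160


# =====================================================================
# Basic information (cleartext section)
# =====================================================================

_BASIC_FIELDS = (
    ("hospital", "Hospital"),
    ("department", "Department"),
    ("doctor_number", "Doctor number"),
    ("patient_number", "Patient number"),
    ("shooting_time", "Shooting time"),
    ("contact_number", "Contact number"),
    ("image_type", "Image type"),
)


@dataclass(frozen=True)
class BasicInfo:
    """Patient/image metadata carried in clear. Empty strings are legal."""

    hospital: str = ""
    department: str = ""
    doctor_number: str = ""
    patient_number: str = ""
    shooting_time: str = ""
    contact_number: str = ""
    image_type: str = ""

    def to_text(self) -> str:
        """Byte-stable ``Label: value`` lines in fixed field order."""
        return "\n".join(f"{label}: {getattr(self, name)}"
                         for name, label in _BASIC_FIELDS)

    @classmethod
    def from_text(cls, text: str) -> "BasicInfo":
        values = {}
        lines = text.split("\n")
        if len(lines) != len(_BASIC_FIELDS):
            raise QRDecodeError("malformed basic-information section")
        for line, (name, label) in zip(lines, _BASIC_FIELDS):
            prefix = f"{label}:"
            if not line.startswith(prefix):
                raise QRDecodeError(f"missing field {label!r}")
            values[name] = line[len(prefix):].lstrip(" ")
        return cls(**values)

    @classmethod
    def from_dict(cls, d: dict) -> "BasicInfo":
        return cls(**{name: str(d.get(name, "")) for name, _ in _BASIC_FIELDS})


# =====================================================================
# Protected parameters (encrypted section)
# =====================================================================

def format_arnold_text(order: int, iterations: int) -> str:
    """Parameter string in the ``"8 × 8 4"`` form."""
    return f"{order} × {order} {iterations}"


def parse_arnold_text(text: str) -> tuple[int, int]:
    parts = text.replace("×", "x").split()
    if len(parts) != 4 or parts[1] != "x":
        raise ValueError(f"unparseable Arnold parameter string {text!r}")
    n1, n2, k = int(parts[0]), int(parts[2]), int(parts[3])
    if n1 != n2:
        raise ValueError("Arnold block must be square")
    return n1, k


def _pack_mask(mask: np.ndarray) -> bytes:
    return np.packbits(mask.astype(np.uint8).ravel()).tobytes()


def _unpack_mask(data: bytes, shape: tuple[int, int]) -> np.ndarray:
    n = shape[0] * shape[1]
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8), count=n)
    return bits.reshape(shape).astype(bool)


@dataclass(frozen=True)
class ProtectedParams:
    """Everything needed to invert the protection, sans original image."""

    arnold_text: str
    key_tile: Tile
    pee_record: PEERecord
    embeddable_mask: np.ndarray = field(repr=False)
    scramble_mask: np.ndarray = field(repr=False)
    image_shape: tuple[int, int]
    block_size: int = 8

    _MAGIC = b"MSPP"
    _VERSION = 1

    def to_bytes(self) -> bytes:
        rec = self.pee_record
        at = self.arnold_text.encode("utf-8")
        gh, gw = self.embeddable_mask.shape
        out = bytearray()
        out += self._MAGIC
        out += struct.pack(">B", self._VERSION)
        out += struct.pack(">H", len(at)) + at
        out += struct.pack(">HHH", self.key_tile.row, self.key_tile.col,
                           self.key_tile.size)
        out += struct.pack(">HH", *self.image_shape)
        out += struct.pack(">B", self.block_size)
        out += struct.pack(">bbB", rec.params.p, rec.params.q,
                           0 if rec.params.layer_order == "even" else 1)
        out += struct.pack(">IB", rec.payload_bits, rec.layers_used)
        out += struct.pack(">HH", gh, gw)
        out += _pack_mask(self.embeddable_mask)
        out += _pack_mask(self.scramble_mask)
        out += struct.pack(">I", len(rec.location_map))
        for r, c in rec.location_map:
            out += struct.pack(">HH", r, c)
        return bytes(out)

    @classmethod
    def from_bytes(cls, data: bytes) -> "ProtectedParams":
        try:
            view = memoryview(data)
            if view[:4] != cls._MAGIC:
                raise ValueError("bad magic")
            if view[4] != cls._VERSION:
                raise ValueError("unknown version")
            off = 5
            (alen,) = struct.unpack_from(">H", view, off); off += 2
            arnold_text = bytes(view[off:off + alen]).decode("utf-8"); off += alen
            kr, kc, ks = struct.unpack_from(">HHH", view, off); off += 6
            h, w = struct.unpack_from(">HH", view, off); off += 4
            (bsz,) = struct.unpack_from(">B", view, off); off += 1
            p, q, lay = struct.unpack_from(">bbB", view, off); off += 3
            payload_bits, layers = struct.unpack_from(">IB", view, off); off += 5
            gh, gw = struct.unpack_from(">HH", view, off); off += 4
            nmask = (gh * gw + 7) // 8
            emb = _unpack_mask(bytes(view[off:off + nmask]), (gh, gw)); off += nmask
            scr = _unpack_mask(bytes(view[off:off + nmask]), (gh, gw)); off += nmask
            (nloc,) = struct.unpack_from(">I", view, off); off += 4
            locmap = []
            for _ in range(nloc):
                r, c = struct.unpack_from(">HH", view, off); off += 4
                locmap.append((r, c))
        except (struct.error, ValueError, IndexError) as exc:
            raise KeyAuthError(f"protected parameters corrupted: {exc}") from exc
        params = PEEParams(p=p, q=q, layer_order="even" if lay == 0 else "odd")
        rec = PEERecord(params=params, payload_bits=payload_bits,
                        location_map=tuple(locmap), layers_used=layers)
        return cls(arnold_text=arnold_text, key_tile=Tile(kr, kc, ks),
                   pee_record=rec, embeddable_mask=emb, scramble_mask=scr,
                   image_shape=(h, w), block_size=bsz)


# =====================================================================
# RSA + hybrid encryption
# =====================================================================

@dataclass(frozen=True)
class RSAPublicKey:
    n: int
    e: int

    @property
    def size_bytes(self) -> int:
        return (self.n.bit_length() + 7) // 8


@dataclass(frozen=True)
class RSAPrivateKey:
    n: int
    e: int
    d: int

    @property
    def public(self) -> RSAPublicKey:
        return RSAPublicKey(self.n, self.e)

    @property
    def size_bytes(self) -> int:
        return (self.n.bit_length() + 7) // 8


def _random_prime(bits: int, rng: Random) -> int:
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | (1 << (bits - 2)) | 1
        if isprime(cand):
            return cand


def generate_keypair(bits: int = 2048, seed: int | None = None):
    """RSA key pair with e = 65537. ``seed`` makes generation reproducible."""
    if bits < 512:
        raise ValueError("modulus below 512 bits cannot wrap a session key")
    rng = Random(seed) if seed is not None else Random(secrets.randbits(256))
    e = 65537
    while True:
        p = _random_prime(bits // 2, rng)
        q = _random_prime(bits - bits // 2, rng)
        if p == q:
            continue
        phi = (p - 1) * (q - 1)
        if phi % e == 0:
            continue
        n = p * q
        d = pow(e, -1, phi)
        priv = RSAPrivateKey(n=n, e=e, d=d)
        return priv.public, priv


def save_key(key, path) -> None:
    """Write a key as a small JSON text file."""
    obj = {"kind": "private" if isinstance(key, RSAPrivateKey) else "public",
           "n": str(key.n), "e": str(key.e)}
    if isinstance(key, RSAPrivateKey):
        obj["d"] = str(key.d)
    Path(path).write_text(json.dumps(obj))


def load_public_key(path) -> RSAPublicKey:
    obj = json.loads(Path(path).read_text())
    return RSAPublicKey(n=int(obj["n"]), e=int(obj["e"]))


def load_private_key(path) -> RSAPrivateKey:
    obj = json.loads(Path(path).read_text())
    if obj.get("kind") != "private" or "d" not in obj:
        raise KeyAuthError(f"{path} is not a private key file")
    return RSAPrivateKey(n=int(obj["n"]), e=int(obj["e"]), d=int(obj["d"]))


_HLEN = 32  # SHA-256


def _mgf1(seed: bytes, length: int) -> bytes:
    out = b""
    counter = 0
    while len(out) < length:
        out += hashlib.sha256(seed + struct.pack(">I", counter)).digest()
        counter += 1
    return out[:length]


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def _oaep_encrypt(message: bytes, pub: RSAPublicKey, rng: Random) -> bytes:
    k = pub.size_bytes
    if len(message) > k - 2 * _HLEN - 2:
        raise ValueError("message too long for RSA-OAEP with this modulus")
    lhash = hashlib.sha256(b"").digest()
    ps = b"\x00" * (k - len(message) - 2 * _HLEN - 2)
    db = lhash + ps + b"\x01" + message
    seed = rng.randbytes(_HLEN)
    masked_db = _xor(db, _mgf1(seed, k - _HLEN - 1))
    masked_seed = _xor(seed, _mgf1(masked_db, _HLEN))
    em = b"\x00" + masked_seed + masked_db
    c = pow(int.from_bytes(em, "big"), pub.e, pub.n)
    return c.to_bytes(k, "big")


def _oaep_decrypt(ciphertext: bytes, priv: RSAPrivateKey) -> bytes:
    k = priv.size_bytes
    if len(ciphertext) != k:
        raise KeyAuthError("RSA block has the wrong length")
    m = pow(int.from_bytes(ciphertext, "big"), priv.d, priv.n)
    em = m.to_bytes(k, "big")
    masked_seed, masked_db = em[1:1 + _HLEN], em[1 + _HLEN:]
    seed = _xor(masked_seed, _mgf1(masked_db, _HLEN))
    db = _xor(masked_db, _mgf1(seed, k - _HLEN - 1))
    lhash = hashlib.sha256(b"").digest()
    if em[0] != 0 or db[:_HLEN] != lhash:
        raise KeyAuthError("OAEP decoding failed (wrong key?)")
    idx = db.find(b"\x01", _HLEN)
    if idx < 0 or any(db[_HLEN:idx]):
        raise KeyAuthError("OAEP padding invalid (wrong key?)")
    return db[idx + 1:]


def _keystream(key: bytes, nonce: bytes, length: int) -> bytes:
    out = b""
    counter = 0
    while len(out) < length:
        out += hashlib.sha256(key + nonce + struct.pack(">Q", counter)).digest()
        counter += 1
    return out[:length]


def _derive(session: bytes) -> tuple[bytes, bytes]:
    return (hashlib.sha256(b"medseal-enc" + session).digest(),
            hashlib.sha256(b"medseal-mac" + session).digest())


def _hybrid_encrypt(plain: bytes, pub: RSAPublicKey, rng: Random) -> bytes:
    session = rng.randbytes(32)
    nonce = rng.randbytes(16)
    enc_key, mac_key = _derive(session)
    ct = _xor(plain, _keystream(enc_key, nonce, len(plain)))
    tag = hmac_mod.new(mac_key, nonce + ct, hashlib.sha256).digest()
    wrap = _oaep_encrypt(session, pub, rng)
    return struct.pack(">H", len(wrap)) + wrap + nonce + ct + tag


def _hybrid_decrypt(blob: bytes, priv: RSAPrivateKey) -> bytes:
    try:
        (wlen,) = struct.unpack_from(">H", blob, 0)
        wrap = blob[2:2 + wlen]
        nonce = blob[2 + wlen:18 + wlen]
        ct, tag = blob[18 + wlen:-32], blob[-32:]
        if len(nonce) != 16 or len(tag) != 32:
            raise KeyAuthError("ciphertext truncated")
    except struct.error as exc:
        raise KeyAuthError("ciphertext malformed") from exc
    session = _oaep_decrypt(wrap, priv)
    enc_key, mac_key = _derive(session)
    expect = hmac_mod.new(mac_key, nonce + ct, hashlib.sha256).digest()
    if not hmac_mod.compare_digest(tag, expect):
        raise KeyAuthError("authentication failed (wrong key or tampering)")
    return _xor(ct, _keystream(enc_key, nonce, len(ct)))


def encrypt_params(params: ProtectedParams, public_key: RSAPublicKey,
                   rng: Random | None = None) -> str:
    """Serialize and hybrid-encrypt the parameters; returns base64 text."""
    rng = rng if rng is not None else Random(secrets.randbits(256))
    blob = _hybrid_encrypt(params.to_bytes(), public_key, rng)
    return base64.b64encode(blob).decode("ascii")


def decrypt_params(ciphertext: str, private_key: RSAPrivateKey) -> ProtectedParams:
    """Invert :func:`encrypt_params`; any failure raises KeyAuthError
    before a single byte of plaintext is exposed."""
    try:
        blob = base64.b64decode(ciphertext.encode("ascii"), validate=True)
    except Exception as exc:
        raise KeyAuthError("ciphertext is not valid base64") from exc
    return ProtectedParams.from_bytes(_hybrid_decrypt(blob, private_key))


# =====================================================================
# Matrix barcode rendering / decoding
# =====================================================================

_QUIET = 4
_BAND_ROWS = 12                      # finder + sync band below the quiet zone
_DATA_R0 = _QUIET + _BAND_ROWS       # 16
_DATA_R1 = QR_SIZE - _QUIET          # 156
_DATA_C0 = _QUIET                    # 4
_DATA_C1 = QR_SIZE - _QUIET          # 156
_DATA_BITS = (_DATA_R1 - _DATA_R0) * (_DATA_C1 - _DATA_C0)   # 21,280
_FRAME_MAGIC = b"MQRC"
_FRAME_VERSION = 1
_FRAME_OVERHEAD = len(_FRAME_MAGIC) + 1 + 4 + 4               # + CRC-32
#: maximum payload the 160x160 symbol can carry, in bytes
QR_CAPACITY_BYTES = _DATA_BITS // 8 - _FRAME_OVERHEAD


def _finder_pattern() -> np.ndarray:
    """12x12 nested-square finder (True = dark), QR-look-alike."""
    f = np.zeros((12, 12), dtype=bool)
    f[:, :] = True
    f[2:10, 2:10] = False
    f[4:8, 4:8] = True
    return f


def _band_pattern() -> np.ndarray:
    """The full (12, 152) finder + sync band (True = dark)."""
    band = np.zeros((_BAND_ROWS, QR_SIZE - 2 * _QUIET), dtype=bool)
    f = _finder_pattern()
    band[:, :12] = f
    band[:, -12:] = f
    cols = np.arange(12, band.shape[1] - 12)
    band[:, 12:-12] = (cols // 2 % 2 == 0)[None, :]   # 2px vertical stripes
    return band


@dataclass(frozen=True)
class QRPayload:
    """Cleartext metadata plus the base64 ciphertext section."""

    basic: BasicInfo
    ciphertext: str

    def to_bytes(self) -> bytes:
        basic = self.basic.to_text().encode("utf-8")
        ct = base64.b64decode(self.ciphertext.encode("ascii"))
        return (struct.pack(">H", len(basic)) + basic
                + struct.pack(">I", len(ct)) + ct)

    @classmethod
    def from_bytes(cls, data: bytes) -> "QRPayload":
        try:
            (blen,) = struct.unpack_from(">H", data, 0)
            basic = data[2:2 + blen].decode("utf-8")
            (clen,) = struct.unpack_from(">I", data, 2 + blen)
            ct = data[6 + blen:6 + blen + clen]
            if len(ct) != clen:
                raise ValueError("truncated ciphertext section")
        except (struct.error, ValueError, UnicodeDecodeError) as exc:
            raise QRDecodeError(f"payload framing invalid: {exc}") from exc
        return cls(basic=BasicInfo.from_text(basic),
                   ciphertext=base64.b64encode(ct).decode("ascii"))


def render_qr(payload: QRPayload) -> np.ndarray:
    """Render the payload as a 160x160 binarized (0/255) code block."""
    body = payload.to_bytes()
    if len(body) > QR_CAPACITY_BYTES:
        raise CapacityError(
            f"payload of {len(body)} bytes exceeds the {QR_CAPACITY_BYTES}-"
            "byte capacity of the 160x160 symbol",
            required=len(body), available=QR_CAPACITY_BYTES)
    frame = (_FRAME_MAGIC + struct.pack(">B", _FRAME_VERSION)
             + struct.pack(">I", len(body)) + body)
    frame += struct.pack(">I", zlib.crc32(frame))
    bits = np.unpackbits(np.frombuffer(frame, dtype=np.uint8))
    pad = np.resize(np.array([0, 1], dtype=np.uint8), _DATA_BITS - bits.size)
    grid = np.concatenate([bits, pad]).reshape(_DATA_R1 - _DATA_R0,
                                               _DATA_C1 - _DATA_C0)

    img = np.full((QR_SIZE, QR_SIZE), 255, dtype=np.uint8)
    band = _band_pattern()
    img[_QUIET:_QUIET + _BAND_ROWS, _QUIET:QR_SIZE - _QUIET] = \
        np.where(band, 0, 255)
    img[_DATA_R0:_DATA_R1, _DATA_C0:_DATA_C1] = np.where(grid == 1, 0, 255)
    return img


def decode_qr(block) -> QRPayload:
    """Decode a 160x160 code block; raises :class:`QRDecodeError` if the
    block is not an intact symbol (tampered, scrambled, or natural image)."""
    arr = as_gray_image(block)
    if arr.shape != (QR_SIZE, QR_SIZE):
        raise QRDecodeError(f"code block must be {QR_SIZE}x{QR_SIZE}, "
                            f"got {arr.shape}")
    dark = arr < 128
    quiet = np.concatenate([
        dark[:_QUIET, :].ravel(), dark[-_QUIET:, :].ravel(),
        dark[:, :_QUIET].ravel(), dark[:, -_QUIET:].ravel()])
    if quiet.any():
        raise QRDecodeError("quiet zone violated; not an intact symbol")
    band = dark[_QUIET:_QUIET + _BAND_ROWS, _QUIET:QR_SIZE - _QUIET]
    if not np.array_equal(band, _band_pattern()):
        raise QRDecodeError("finder/sync band mismatch; symbol damaged "
                            "or illegally altered")
    bits = dark[_DATA_R0:_DATA_R1, _DATA_C0:_DATA_C1].ravel().astype(np.uint8)
    raw = np.packbits(bits).tobytes()
    if raw[:4] != _FRAME_MAGIC or raw[4] != _FRAME_VERSION:
        raise QRDecodeError("frame header missing")
    (length,) = struct.unpack_from(">I", raw, 5)
    if length > QR_CAPACITY_BYTES:
        raise QRDecodeError("frame length field corrupted")
    end = 9 + length
    (crc,) = struct.unpack_from(">I", raw, end)
    if zlib.crc32(raw[:end]) != crc:
        raise QRDecodeError("CRC mismatch; symbol corrupted")
    return QRPayload.from_bytes(raw[9:end])


def locate_qr(image) -> tuple[Tile, QRPayload]:
    """Find and decode the code block anywhere in an image.

    The 160-grid anchor positions are tried first (the automatic
    placement), then an exhaustive finder-pattern search covers
    clinician-overridden off-grid placements.
    """
    arr = as_gray_image(image)
    h, w = arr.shape
    for r in range(0, h - QR_SIZE + 1, QR_SIZE):
        for c in range(0, w - QR_SIZE + 1, QR_SIZE):
            try:
                blk = arr[r:r + QR_SIZE, c:c + QR_SIZE]
                return Tile(r, c, QR_SIZE), decode_qr(blk)
            except QRDecodeError:
                continue
    finder = _finder_pattern()
    dark = arr < 128
    if h >= 12 and w >= 12:
        win = np.lib.stride_tricks.sliding_window_view(dark, (12, 12))
        hits = np.all(win == finder, axis=(2, 3))
        for fr, fc in np.argwhere(hits):
            r, c = int(fr) - _QUIET, int(fc) - _QUIET
            if 0 <= r <= h - QR_SIZE and 0 <= c <= w - QR_SIZE:
                try:
                    blk = arr[r:r + QR_SIZE, c:c + QR_SIZE]
                    return Tile(r, c, QR_SIZE), decode_qr(blk)
                except QRDecodeError:
                    continue
    raise QRDecodeError("no decodable code block found; the image was "
                        "illegally destroyed or never protected")
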