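# Methods

This note documents the model implemented by `medseal`, the choices made
where the design was genuinely open, and what the synthetic test images
do and do not establish.

## Pipeline model and assumptions

The carrier is an 8-bit grayscale raster; 512×512 is the canonical size
(512 = 3·160 + 32, so the 160-grid of key-region candidates leaves a
32-pixel residual margin at the right/bottom that is excluded from
key-region candidacy; the 8×8 texture grid tiles the image exactly).
Coordinates are 0-based, row-major, top-left origin; tiles are half-open
`[r, r+b) × [c, c+b)`. Color or >8-bit input is rejected rather than
converted — silent conversion would break the bit-exactness contract.

The protection assumes a *single* sensitive region per image, that
texture (coefficient of variation) is an adequate proxy for diagnostic
content, and that the non-sensitive texture area is large enough to
carry the region's own 204,800-bit payload. The last assumption is
structural: with one bit per carrier pixel, at least ~3,300 of the 4,096
8×8 tiles must be texture-classified and outside the key region. Images
that violate it fail loudly with a capacity error.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| key region side | 160 | px | large enough to localize a lesion, small enough that the payload can fit in the remaining texture |
| texture block side | 8 | px | one grid serves texture scoring, embedding, and Arnold scrambling, keeping the three tile sets aligned |
| threshold `T` | 5 | squared gray levels | the smallest value of the conventional 5..50 sweep family; maximizes embeddable area |
| error range `[p, q]` | `[−2, 2]`, auto-widened to at most `[−20, 20]` | gray levels | narrow ranges minimize distortion; the encoder widens symmetrically until the payload fits and records the chosen range |
| Arnold iterations `k` | 4 | steps | the conventional worked value (`"8 × 8 4"`); any `0 ≤ k` works, applied modulo the period (6 for order 8) |
| RSA modulus | 2048 | bits | current practice for key wrapping |
| SSIM window | 8×8 uniform, `K1=0.01, K2=0.03, L=255` | — | window matched to the texture block size; constants standard |

## Numerical conventions

* `⌊·⌋` is floor toward −∞ and `mod` is the always-non-negative
  mathematical residue, for negative operands too. The prediction error
  is computed in exact integer arithmetic as `d = (S − 4v) >> 2` with
  `S` the neighbour sum.
* The stego update is the unique integral rule consistent with the
  floor: `v' = v + (d − D)`. Writing `u − v' = D + frac(u − v)` shows
  `⌊u − v'⌋ = D` exactly, so decoding recovers `D`, and
  `v = v' + (D − d)` restores the pixel in every case (expanded or
  shifted).
* `C_v` is defined as 0 when `μ = 0`, so all-black blocks can never win
  the key-region argmax. Ties in the argmax and in MSE ordering break by
  row-major tile index; the embeddable list is reported in ascending-MSE
  order, the field's convention for such maps.
* PSNR uses MAX = 255 over all pixels and reports `inf` at zero MSE.
  SSIM uses population (biased) window statistics; the test suite
  cross-checks against scikit-image configured identically apart from
  its odd-window requirement.

## Embedding design

**Eligibility.** A pixel is an embedding target iff it lies in an
embeddable tile, all four diamond neighbours are inside the image, and
no neighbour lies inside the one-pixel-dilated key region. Prediction
deliberately crosses 8×8 tile boundaries: scrambling is inverted before
extraction, so cross-tile predictors are safe, and restricting targets
to tile interiors (6×6 of 64) would cap capacity at 133,056 bits —
arithmetically below the 204,800-bit key-region stream. Predictors may
not reach into the key region because its content is replaced by the
code block and is unavailable at extraction time.

**Two global checkerboard passes.** All `(row+col)`-even targets are
embedded first, then all odd ones; a pixel's four predictors always
have opposite parity, so pass-1 predictors are untouched during pass 1
and pass-2 predictors are stable during pass 2. Extraction replays odd
then even. Within a pass, payload bits fill carriers in row-major
order — an order reconstructible from the carried tile mask alone,
with no need to transmit MSE ranks.

**Whole-area processing.** Every eligible pixel of every embeddable
tile is processed: in-range errors are expanded (the payload is
zero-padded up to capacity), out-of-range errors are shifted. Leaving
post-payload in-range pixels untouched would make them indistinguishable
from expanded ones at decode time and break reversibility; whole-area
processing is also what makes quality rise with the threshold (fewer
blocks processed → less distortion), the behaviour the threshold sweep
measures.

**Overflow.** Pixels whose modified value would leave [0, 255] — for
carriers, under either bit value — are skipped and recorded in a
location map carried in the protected parameters. On the synthetic
images the map is empty (intensities sit well inside the range), but
reversibility at saturation requires it in general.

**Capacity semantics.** `capacity()` counts carriers statically on the
unmodified image; the realized two-pass figure can differ by a handful
of pixels because pass-1 writes perturb pass-2 predictions. The encoder
treats the static count as a pre-filter and `embed_stream` as the
authority, widening the range on shortfall.

## Scrambling and side-information

The Arnold map is applied per 8×8 tile to the *embedded* (texture) tile
set — the set the threshold actually selects — and the exact set is
carried in the encrypted parameters. Tiles with `MSE > 0` form the
scramble-candidate classification, but scrambling a tile that carries no
hidden data adds no protection to the payload while decoupling the
quality curve from the threshold; at the default `T = 5` the two sets
coincide on all but near-flat background tiles. Carrying the tile masks
(rather than recomputing MSE on the modified image at decode time, which
shifts can push across the threshold) guarantees encoder/decoder
agreement and the lossless contract. Unscrambling by the inverse matrix
`[[2, −1], [−1, 1]] mod N` agrees with completing the period, and both
are tested.

## The code block

No ISO/IEC 18004 implementation is available as a dependency, so the
replacement block is a compact synthetic matrix symbology designed for
this package: 4-px quiet zone, two nested-square finders plus a striped
sync band, and a CRC-32-framed data field at one pixel per module
(≈2.6 KB capacity). On the lossless digital channel this is exactly
equivalent in role to a QR symbol — cleartext metadata plus ciphertext,
decodable when intact, failing loudly when scrambled or overwritten —
but a general-purpose QR reader will not decode it; swapping in a
standard symbology is a drop-in change behind `render_qr`/`decode_qr`.

Parameter encryption is hybrid because textbook RSA cannot hold the tile
masks and location map: a fresh 256-bit session key is RSA-OAEP-wrapped
(SHA-256), the serialized parameters are encrypted with a SHA-256
counter keystream, and an HMAC-SHA256 tag authenticates the result, so a
wrong key fails closed before any plaintext or image processing. Keys
are stored as JSON integer files, not PEM.

## Threshold sweep

The sweep holds the error range fixed (chosen once, wide enough for the
largest threshold's texture area) so per-pixel distortion is comparable
across thresholds, and re-seeds the session material identically per
threshold so two thresholds selecting the same texture area produce the
same image. Quality is then non-decreasing in `T` up to a ±0.01 dB
ripple caused by the differing ciphertext bit patterns in the code
block, and the curve plateaus exactly once no block MSE lies between
successive thresholds.

## The phantom and what it shows

The generator emulates the selection criteria of curated CT evaluation
sets: an organ filling ~95% of the frame, band-limited noise texture
(3×3-smoothed Gaussian) whose blocks are texture-classified at every
sweep threshold, a rectangular band of tiles with MSEs spread over 8..40
(renormalized per tile, leaving the interval (45, 50] empty so the sweep
plateau is observable), near-flat dark corners, and a bimodal
high-contrast lesion filling one 160-grid tile whose `C_v` dominates by
construction. Generation is seed-deterministic and post-verified against
the dominance and capacity invariants.

The phantom is *not* anatomically realistic: real scans have saturated
regions (exercising the location map), texture that fails the capacity
assumption at high thresholds, and lesions that do not fill a grid tile.
Passing tests therefore demonstrate the algorithmic contracts —
losslessness, invertibility, degradation without the key, trend
direction — not clinical detection performance.

## Known limitations

* Single key region per image; multi-region protection is out of scope.
* The capacity assumption binds: at one bit per pixel a 512×512 carrier
  cannot protect a 160×160 region unless ~90% of its non-key tiles are
  texture; no multi-pass embedding is attempted.
* The code block is not readable by off-the-shelf QR scanners (above).
* The crypto primitives are assembled from hash functions and modular
  arithmetic for self-containedness; production deployments should swap
  in a vetted cryptography library behind the same interfaces.
* DICOM files are not read or written; convert to 8-bit PNG/PGM first.
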