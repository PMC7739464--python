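"""Exception hierarchy shared across the package.

Distinct classes exist so the CLI can map failure modes to distinct exit
codes (capacity, barcode decode, key/authentication).
"""


class MedSealError(Exception):
    """Base class for all package errors."""


class FormatError(MedSealError):
    """Input image is not 8-bit grayscale, or a file is malformed."""


class CapacityError(MedSealError):
    """A payload does not fit the available embedding or barcode capacity."""

    def __init__(self, message: str, required: int | None = None,
                 available: int | None = None):
        super().__init__(message)
        self.required = required
        self.available = available


class QRDecodeError(MedSealError):
    """The 160x160 code block cannot be decoded (tampered or not a code)."""


class KeyAuthError(MedSealError):
    """Decryption failed: wrong key or corrupted ciphertext."""


class IntegrityError(MedSealError):
    """Embedding side-information is inconsistent with the image."""


class GenerationError(MedSealError):
    """A phantom specification cannot be satisfied."""
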