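"""XOR stream-cipher demonstration and NPCR/UACI diffusion metrics.

The keystream bytes are XORed pixel-wise with an 8-bit grayscale plaintext:
``c = s ⊕ m``.  NPCR (number of pixels changed rate) and UACI (unified
average changed intensity) compare two ciphertexts whose plaintexts differ
in one bit, with analytic acceptance thresholds for image size MN and
grey-level maximum F:

    NPCR critical   100·(F − z_α·sqrt(F/MN)) / (F + 1)
    UACI mean       μ = (F + 2) / (3F + 3)
    UACI variance   σ² = (F + 2)(F² + 2F + 3) / (18 (F + 1)² F MN)
    UACI bounds     100·(μ ∓ z_{α/2}·σ)

A plain XOR cipher has no diffusion: flipping one plaintext bit under a
shared keystream changes exactly one ciphertext pixel, far below the NPCR
threshold.  The diffusion experiment therefore supports both the literal
shared-keystream mode and an independent-keystream-per-plaintext mode,
which is the regime the analytic thresholds are designed for (each
ciphertext pair then behaves as two independent uniform images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_io import ByteStream, read_pgm, write_pgm

__all__ = [
    "GrayImage",
    "DiffusionResult",
    "xor_encrypt",
    "npcr",
    "uaci",
    "npcr_critical",
    "uaci_bounds",
    "diffusion_experiment",
]


@dataclass
class GrayImage:
    """8-bit grayscale image; pixels row-major."""

    width: int
    height: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
                raise ValueError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        self.pixels = self.pixels.ravel()
        if self.pixels.size != self.width * self.height:
            raise ValueError(
                f"expected {self.width * self.height} pixels, got {self.pixels.size}"
            )

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @classmethod
    def from_pgm(cls, path) -> "GrayImage":
        w, h, px = read_pgm(path)
        return cls(width=w, height=h, pixels=px)

    def to_pgm(self, path) -> None:
        write_pgm(ByteStream(self.pixels), self.width, self.height, path)


def xor_encrypt(image: GrayImage, keystream: ByteStream) -> GrayImage:
    """Pixel-wise XOR with the first width×height keystream bytes."""
    if len(keystream) < image.n_pixels:
        raise ValueError(
            f"keystream has {len(keystream)} bytes; image needs {image.n_pixels}"
        )
    cipher = image.pixels ^ keystream.data[: image.n_pixels]
    return GrayImage(width=image.width, height=image.height, pixels=cipher)


def _check_dims(c1: GrayImage, c2: GrayImage) -> None:
    if (c1.width, c1.height) != (c2.width, c2.height):
        raise ValueError("image dimensions differ")


def npcr(c1: GrayImage, c2: GrayImage) -> float:
    """Percentage of pixel positions whose values differ."""
    _check_dims(c1, c2)
    return float(100.0 * np.count_nonzero(c1.pixels != c2.pixels) / c1.n_pixels)


def uaci(c1: GrayImage, c2: GrayImage) -> float:
    """Mean absolute intensity change as a percentage of full scale."""
    _check_dims(c1, c2)
    diff = np.abs(c1.pixels.astype(np.int16) - c2.pixels.astype(np.int16))
    return float(100.0 * diff.mean() / 255.0)


def npcr_critical(alpha: float, max_val: int = 255, n_pixels: int = 65536) -> float:
    """One-sided NPCR acceptance threshold (percent) at level ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    f = float(max_val)
    z = stats.norm.isf(alpha)
    return 100.0 * (f - z * np.sqrt(f / n_pixels)) / (f + 1.0)


def uaci_bounds(alpha: float, max_val: int = 255, n_pixels: int = 65536) -> tuple[float, float]:
    """Two-sided UACI acceptance interval (percent) at level ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    f = float(max_val)
    mu = (f + 2.0) / (3.0 * f + 3.0)
    var = (f + 2.0) * (f * f + 2.0 * f + 3.0) / (18.0 * (f + 1.0) ** 2 * f * n_pixels)
    z = stats.norm.isf(alpha / 2.0)
    sigma = np.sqrt(var)
    return 100.0 * (mu - z * sigma), 100.0 * (mu + z * sigma)


@dataclass(frozen=True)
class DiffusionResult:
    npcr_pct: float
    uaci_pct: float
    npcr_critical_pct: float
    uaci_low_pct: float
    uaci_high_pct: float

    @property
    def npcr_pass(self) -> bool:
        return self.npcr_pct >= self.npcr_critical_pct

    @property
    def uaci_pass(self) -> bool:
        return self.uaci_low_pct <= self.uaci_pct <= self.uaci_high_pct

    def as_dict(self) -> dict:
        return {
            "npcr_pct": self.npcr_pct,
            "uaci_pct": self.uaci_pct,
            "npcr_critical_pct": self.npcr_critical_pct,
            "uaci_low_pct": self.uaci_low_pct,
            "uaci_high_pct": self.uaci_high_pct,
            "npcr_pass": self.npcr_pass,
            "uaci_pass": self.uaci_pass,
        }


def diffusion_experiment(
    plain: GrayImage,
    keystream: ByteStream,
    alpha: float = 0.05,
    keystream2: ByteStream | None = None,
    flip_pixel: tuple[int, int] = (0, 0),
    flip_bit: int = 0,
) -> DiffusionResult:
    """NPCR/UACI between the ciphertexts of a plaintext and its one-bit variant.

    With ``keystream2 = None`` both plaintexts are encrypted under the same
    keystream (the literal XOR construction, which cannot pass — one flipped
    plaintext bit changes exactly one ciphertext pixel); passing a second,
    independent keystream reproduces the regime the analytic thresholds
    describe.
    """
    row, col = flip_pixel
    if not (0 <= row < plain.height and 0 <= col < plain.width):
        raise ValueError("flip_pixel outside the image")
    if not 0 <= flip_bit < 8:
        raise ValueError("flip_bit must lie in [0, 8)")
    altered = plain.pixels.copy()
    altered[row * plain.width + col] ^= np.uint8(1 << flip_bit)
    plain2 = GrayImage(width=plain.width, height=plain.height, pixels=altered)

    c1 = xor_encrypt(plain, keystream)
    c2 = xor_encrypt(plain2, keystream2 if keystream2 is not None else keystream)
    lo, hi = uaci_bounds(alpha, 255, plain.n_pixels)
    return DiffusionResult(
        npcr_pct=npcr(c1, c2),
        uaci_pct=uaci(c1, c2),
        npcr_critical_pct=npcr_critical(alpha, 255, plain.n_pixels),
        uaci_low_pct=lo,
        uaci_high_pct=hi,
    )
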