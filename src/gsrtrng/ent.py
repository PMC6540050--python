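"""Byte-stream randomness statistics in the style of the classic ENT suite.

Six quantities: Shannon entropy (bits/byte), optimum compression percentage,
Pearson chi-square against the uniform byte distribution with its exceed
probability, arithmetic mean, Monte-Carlo π and serial correlation.

Conventions: serial correlation is circular (the last byte pairs with the
first); the chi-square exceed probability uses the exact χ²₂₅₅ survival
function rather than a lookup table; the Monte-Carlo π inside test is done
in integer arithmetic (``x² + y² ≤ (2²⁴−1)²``) so the circle boundary is
unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signal_io import ByteStream

__all__ = [
    "EntReport",
    "byte_entropy",
    "chi_square_bytes",
    "arithmetic_mean",
    "monte_carlo_pi",
    "serial_correlation",
    "ent_report",
]

_MC_RADIUS_SQ = (2**24 - 1) ** 2


@dataclass(frozen=True)
class EntReport:
    entropy_bits_per_byte: float
    optimum_compression_pct: float
    chi_square: float
    chi_square_exceed_pct: float
    arithmetic_mean: float
    monte_carlo_pi: float
    monte_carlo_pi_error_pct: float
    serial_correlation: float | None  # None when the stream has zero variance

    def as_dict(self) -> dict:
        return {
            "entropy_bits_per_byte": self.entropy_bits_per_byte,
            "optimum_compression_pct": self.optimum_compression_pct,
            "chi_square": self.chi_square,
            "chi_square_exceed_pct": self.chi_square_exceed_pct,
            "arithmetic_mean": self.arithmetic_mean,
            "monte_carlo_pi": self.monte_carlo_pi,
            "monte_carlo_pi_error_pct": self.monte_carlo_pi_error_pct,
            "serial_correlation": self.serial_correlation,
        }


def _counts(stream: ByteStream) -> np.ndarray:
    if len(stream) == 0:
        raise ValueError("empty byte stream")
    return np.bincount(stream.data, minlength=256)


def byte_entropy(stream: ByteStream) -> float:
    """Shannon entropy of the empirical byte distribution, bits per byte."""
    counts = _counts(stream)
    p = counts[counts > 0] / len(stream)
    return float(-np.sum(p * np.log2(p)))


def chi_square_bytes(stream: ByteStream) -> tuple[float, float]:
    """Pearson χ² vs. uniform over the 256 byte values (255 df).

    Returns ``(statistic, exceed_pct)`` where ``exceed_pct`` is
    ``100 · P(χ²₂₅₅ > statistic)``.
    """
    counts = _counts(stream)
    expected = len(stream) / 256.0
    statistic = float(np.sum((counts - expected) ** 2) / expected)
    exceed = float(100.0 * stats.chi2.sf(statistic, df=255))
    return statistic, exceed


def arithmetic_mean(stream: ByteStream) -> float:
    """Mean byte value; 127.5 for an unbiased stream."""
    if len(stream) == 0:
        raise ValueError("empty byte stream")
    return float(stream.data.mean())


def monte_carlo_pi(stream: ByteStream) -> tuple[float, float]:
    """π estimate from non-overlapping 6-byte points in the 24-bit square.

    Each 6-byte group yields big-endian 24-bit coordinates (x, y); the point
    is inside when ``x² + y² ≤ (2²⁴−1)²``; the estimate is 4·inside/total.
    """
    n_pts = len(stream) // 6
    if n_pts < 1:
        raise ValueError("need at least 6 bytes for a Monte-Carlo point")
    b = stream.data[: n_pts * 6].reshape(n_pts, 6).astype(np.uint64)
    x = (b[:, 0] << np.uint64(16)) | (b[:, 1] << np.uint64(8)) | b[:, 2]
    y = (b[:, 3] << np.uint64(16)) | (b[:, 4] << np.uint64(8)) | b[:, 5]
    inside = int(np.count_nonzero(x * x + y * y <= _MC_RADIUS_SQ))
    est = 4.0 * inside / n_pts
    err = 100.0 * abs(est - math.pi) / math.pi
    return est, err


def serial_correlation(stream: ByteStream) -> float | None:
    """Circular lag-1 correlation of byte values; ``None`` if variance is 0."""
    if len(stream) < 2:
        raise ValueError("need at least 2 bytes")
    x = stream.data.astype(np.float64)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return None
    return float(np.dot(xc, np.roll(xc, -1)) / denom)


def ent_report(stream: ByteStream) -> EntReport:
    """All six statistics on one stream (requires >= 6 bytes)."""
    if len(stream) < 6:
        raise ValueError("need at least 6 bytes for a full report")
    h = byte_entropy(stream)
    chi, exceed = chi_square_bytes(stream)
    pi_est, pi_err = monte_carlo_pi(stream)
    return EntReport(
        entropy_bits_per_byte=h,
        optimum_compression_pct=(8.0 - h) / 8.0 * 100.0,
        chi_square=chi,
        chi_square_exceed_pct=exceed,
        arithmetic_mean=arithmetic_mean(stream),
        monte_carlo_pi=pi_est,
        monte_carlo_pi_error_pct=pi_err,
        serial_correlation=serial_correlation(stream),
    )
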