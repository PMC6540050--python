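"""SP 800-22-style statistical tests on bit sequences.

Implements the three closed-form tests (monobit frequency, block frequency,
runs), the multi-sequence minimum-pass-rate rule

    mpr = floor(K · [(1 − α) − 3·sqrt(α(1 − α)/K)])

(96 of 100 sequences at α = 0.01), and a Kolmogorov–Smirnov test of the
uniformity of the per-sequence p-values.  The remaining SP 800-22 tests are
run externally on streams exported with ``signal_io.write_bits``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "SuiteResult",
    "monobit_frequency",
    "block_frequency",
    "runs_test",
    "min_pass_rate",
    "ks_uniformity",
    "run_suite",
]

DEFAULT_BLOCK_LEN = 128


def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    if arr.size and arr.max() > 1:
        raise ValueError("input must be a 0/1 sequence")
    return arr


def monobit_frequency(bits) -> float:
    """Frequency (monobit) test: p = erfc(|#1 − #0| / sqrt(2n))."""
    b = _as_bits(bits)
    n = b.size
    if n < 100:
        raise ValueError("need at least 100 bits")
    s = abs(2 * int(np.count_nonzero(b)) - n) / math.sqrt(n)
    return float(special.erfc(s / math.sqrt(2)))


def block_frequency(bits, block_len: int = DEFAULT_BLOCK_LEN) -> float:
    """Block-frequency test: χ² of per-block one-proportions around 1/2."""
    if block_len < 8:
        raise ValueError("block_len must be >= 8")
    b = _as_bits(bits)
    n_blocks = b.size // block_len
    if n_blocks < 1:
        raise ValueError("need at least one full block")
    pi = b[: n_blocks * block_len].reshape(n_blocks, block_len).mean(axis=1)
    chi2 = 4.0 * block_len * float(np.sum((pi - 0.5) ** 2))
    return float(special.gammaincc(n_blocks / 2.0, chi2 / 2.0))


def runs_test(bits) -> float:
    """Runs test; by convention p = 0 when the monobit prerequisite
    (|π̂ − 1/2| < 2/sqrt(n)) fails."""
    b = _as_bits(bits)
    n = b.size
    if n < 100:
        raise ValueError("need at least 100 bits")
    pi_hat = float(np.count_nonzero(b)) / n
    if abs(pi_hat - 0.5) >= 2.0 / math.sqrt(n):
        return 0.0
    v = 1 + int(np.count_nonzero(b[1:] != b[:-1]))
    num = abs(v - 2.0 * n * pi_hat * (1 - pi_hat))
    den = 2.0 * math.sqrt(2.0 * n) * pi_hat * (1 - pi_hat)
    return float(special.erfc(num / den))


def min_pass_rate(alpha: float, k: int) -> int:
    """Minimum number of the ``k`` sequences that must pass at level ``alpha``.

    Three-sigma binomial bound on the pass proportion, floored to a count.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    prop = (1.0 - alpha) - 3.0 * math.sqrt(alpha * (1.0 - alpha) / k)
    return int(math.floor(k * prop))


def ks_uniformity(p_values) -> float:
    """One-sample Kolmogorov–Smirnov p-value against Uniform(0, 1)."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size < 5:
        raise ValueError("need at least 5 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(stats.kstest(p, "uniform").pvalue)


@dataclass(frozen=True)
class SuiteResult:
    """Per-test outcome over a set of sequences."""

    test_name: str
    per_sequence_p: np.ndarray
    proportion_passing: int
    min_pass_rate: int
    ks_p: float

    @property
    def proportion_ok(self) -> bool:
        return self.proportion_passing >= self.min_pass_rate

    def as_dict(self) -> dict:
        return {
            "test": self.test_name,
            "p_values": self.per_sequence_p.tolist(),
            "proportion_passing": self.proportion_passing,
            "min_pass_rate": self.min_pass_rate,
            "proportion_ok": self.proportion_ok,
            "ks_p": self.ks_p,
        }


_TESTS = {
    "frequency": monobit_frequency,
    "block_frequency": block_frequency,
    "runs": runs_test,
}


def run_suite(streams, alpha: float = 0.01, block_len: int = DEFAULT_BLOCK_LEN) -> dict[str, SuiteResult]:
    """Run the implemented tests on every sequence and apply the pass-rate
    rule and the p-value uniformity check per test."""
    streams = [_as_bits(s) for s in streams]
    if len(streams) < 2:
        raise ValueError("need at least 2 sequences")
    mpr = min_pass_rate(alpha, len(streams))
    out: dict[str, SuiteResult] = {}
    for name, fn in _TESTS.items():
        if name == "block_frequency":
            p = np.array([fn(s, block_len) for s in streams])
        else:
            p = np.array([fn(s) for s in streams])
        out[name] = SuiteResult(
            test_name=name,
            per_sequence_p=p,
            proportion_passing=int(np.count_nonzero(p >= alpha)),
            min_pass_rate=mpr,
            ks_p=ks_uniformity(p),
        )
    return out
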