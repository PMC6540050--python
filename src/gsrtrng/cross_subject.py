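"""Cross-subject analyses: per-subject byte-frequency bias and pairwise
Hamming-distance comparison against the Binomial(m, 1/2) null.

If the bitstreams generated from different subjects' signals are unrelated
fair coin flips, the Hamming distance between aligned m-bit words of any
two subjects follows Binomial(m, 1/2): mean m/2, variance m/4.  A subject
whose stream is biased or correlated with another's shows up as a byte
chi-square outlier or as a distance distribution shifted away from m/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .ent import chi_square_bytes
from .signal_io import ByteStream

__all__ = ["ChiSquareSummary", "HammingReport", "per_subject_chisq", "hamming_analysis"]

_WORD_DTYPES = {8: np.uint8, 16: np.uint16, 32: np.uint32, 64: np.uint64}


@dataclass(frozen=True)
class ChiSquareSummary:
    per_subject: np.ndarray  # chi-square statistic per subject
    mean: float
    sd: float
    frac_within_1sd: float
    reference_df: int = 255  # χ² degrees of freedom (the theoretical centre)

    def as_dict(self) -> dict:
        return {
            "per_subject": self.per_subject.tolist(),
            "mean": self.mean,
            "sd": self.sd,
            "frac_within_1sd": self.frac_within_1sd,
            "reference_df": self.reference_df,
        }


def per_subject_chisq(cohort_streams: list[ByteStream], min_bytes: int = 10_000) -> ChiSquareSummary:
    """Byte chi-square per subject plus a dispersion summary.

    Under the null each statistic is χ²₂₅₅ (mean 255, sd ≈ 22.6); subjects
    far outside the cohort mean ± 1 sd band are bias suspects.
    """
    if len(cohort_streams) < 2:
        raise ValueError("need at least 2 subjects")
    for i, s in enumerate(cohort_streams):
        if len(s) < min_bytes:
            raise ValueError(f"stream {i} has {len(s)} bytes; need >= {min_bytes}")
    chis = np.array([chi_square_bytes(s)[0] for s in cohort_streams])
    mean = float(chis.mean())
    sd = float(chis.std(ddof=1))
    within = float(np.mean(np.abs(chis - mean) <= sd)) if sd > 0 else 1.0
    return ChiSquareSummary(per_subject=chis, mean=mean, sd=sd, frac_within_1sd=within)


@dataclass(frozen=True)
class HammingReport:
    word_bits: int
    pair_distances: dict  # (i, j) -> np.ndarray of per-word distances
    empirical_mean: float
    empirical_var: float
    gof_p: float

    @property
    def expected_mean(self) -> float:
        return self.word_bits / 2.0

    @property
    def expected_var(self) -> float:
        return self.word_bits / 4.0

    def as_dict(self) -> dict:
        return {
            "word_bits": self.word_bits,
            "empirical_mean": self.empirical_mean,
            "empirical_var": self.empirical_var,
            "expected_mean": self.expected_mean,
            "expected_var": self.expected_var,
            "gof_p": self.gof_p,
            "n_pairs": len(self.pair_distances),
        }


def _to_words(stream: ByteStream, word_bits: int, n_words: int) -> np.ndarray:
    dtype = _WORD_DTYPES[word_bits]
    nbytes = n_words * (word_bits // 8)
    return stream.data[:nbytes].view(dtype)


def _binomial_gof(distances: np.ndarray, m: int) -> float:
    """χ² goodness of fit to Binomial(m, 1/2), pooling bins to expected ≥ 5."""
    n = distances.size
    observed = np.bincount(distances.astype(np.int64), minlength=m + 1).astype(np.float64)
    expected = n * stats.binom.pmf(np.arange(m + 1), m, 0.5)
    # pool sparse tail bins from both ends
    lo = 0
    while lo < m and expected[: lo + 1].sum() < 5:
        lo += 1
    hi = m
    while hi > lo and expected[hi:].sum() < 5:
        hi -= 1
    obs = np.concatenate(
        ([observed[: lo + 1].sum()], observed[lo + 1 : hi], [observed[hi:].sum()])
    )
    exp = np.concatenate(
        ([expected[: lo + 1].sum()], expected[lo + 1 : hi], [expected[hi:].sum()])
    )
    statistic = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(statistic, df=obs.size - 1))


def hamming_analysis(cohort_streams: list[ByteStream], word_bits: int = 64) -> HammingReport:
    """Positional word-wise Hamming distances over all unordered pairs.

    Streams are truncated to the shortest whole-word length; word i of one
    subject is compared with word i of the other.
    """
    if word_bits not in _WORD_DTYPES:
        raise ValueError(f"word_bits must be one of {sorted(_WORD_DTYPES)}")
    if len(cohort_streams) < 2:
        raise ValueError("need at least 2 subjects")
    n_words = min(len(s) for s in cohort_streams) // (word_bits // 8)
    if n_words < 1:
        raise ValueError("streams shorter than one word")
    words = [_to_words(s, word_bits, n_words) for s in cohort_streams]
    pair_distances: dict[tuple[int, int], np.ndarray] = {}
    total = 0.0
    total_sq = 0.0
    count = 0
    for i, j in combinations(range(len(words)), 2):
        d = np.bitwise_count(words[i] ^ words[j]).astype(np.int64)
        pair_distances[(i, j)] = d
        total += float(d.sum())
        total_sq += float((d.astype(np.float64) ** 2).sum())
        count += d.size
    mean = total / count
    var = total_sq / count - mean**2
    all_d = np.concatenate(list(pair_distances.values()))
    return HammingReport(
        word_bits=word_bits,
        pair_distances=pair_distances,
        empirical_mean=mean,
        empirical_var=var,
        gof_p=_binomial_gof(all_d, word_bits),
    )
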