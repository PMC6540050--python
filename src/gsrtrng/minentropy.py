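"""SP 800-90B-style min-entropy assessment of binary sequences.

Three estimators are implemented — most common value, collision and a
first-order Markov estimate — each returning bits of min-entropy per bit,
with the overall assessment being their minimum (the conservative rule for
entropy sources).  A restart sanity check compares the assessment of the
row-major and column-major readings of a restart matrix, catching sources
that replay the same output after every restart.

Upper confidence bounds on estimated probabilities use the 99% normal
bound ``p_u = min(1, p̂ + 2.576·sqrt(p̂(1−p̂)/(n−1)))``.

For a binary i.i.d. source the mean time-to-first-collision is exactly
``E[t] = 2 + 2p(1−p)`` (collision at the 2nd symbol with probability
``p² + q²``, otherwise certain at the 3rd), so the collision estimate
inverts this closed form at the lower confidence bound of the observed
mean; when the bound exceeds the curve's maximum 2.5 no solution exists
and the estimate falls back to the full 1 bit/bit, as in SP 800-90B.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MinEntropyReport",
    "RestartMatrix",
    "RestartResult",
    "mcv_estimate",
    "collision_estimate",
    "markov_estimate_binary",
    "assess",
    "restart_check",
]

_Z99 = 2.576  # upper 99% normal quantile used by the 90B estimators
_PATH_LEN = 128


def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits, dtype=np.uint8).ravel()
    if arr.size and arr.max() > 1:
        raise ValueError("input must be a 0/1 sequence")
    return arr


def _upper_bound(p_hat: float, n: int) -> float:
    if n < 2:
        return 1.0
    return min(1.0, p_hat + _Z99 * math.sqrt(max(p_hat * (1 - p_hat), 0.0) / (n - 1)))


@dataclass(frozen=True)
class MinEntropyReport:
    mcv: float
    collision: float
    markov: float

    @property
    def overall(self) -> float:
        return min(self.mcv, self.collision, self.markov)

    def as_dict(self) -> dict:
        return {
            "mcv": self.mcv,
            "collision": self.collision,
            "markov": self.markov,
            "overall": self.overall,
        }


def mcv_estimate(bits) -> float:
    """Most-common-value estimate: −log2 of the upper confidence bound on
    the most likely symbol's probability."""
    b = _as_bits(bits)
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 bits")
    p_hat = max(np.count_nonzero(b), n - np.count_nonzero(b)) / n
    p_u = _upper_bound(p_hat, n)
    return float(min(1.0, max(0.0, -math.log2(p_u))))


def _collision_times(b: np.ndarray) -> np.ndarray:
    """Times to first collision over successive disjoint scans.

    For a binary alphabet each scan ends at the 2nd symbol (if it repeats
    the 1st) or the 3rd (a collision is then certain), so t ∈ {2, 3}.
    """
    eq = (b[:-1] == b[1:]).tobytes()  # bytes for fast scalar indexing
    n = b.size
    times = []
    i = 0
    while i + 1 < n:
        if eq[i]:
            times.append(2)
            i += 2
        else:
            if i + 2 >= n:
                break
            times.append(3)
            i += 3
    return np.asarray(times, dtype=np.float64)


def collision_estimate(bits) -> float:
    """Collision estimate for binary input.

    Inverts the closed-form mean collision time ``2 + 2p(1−p)`` at the
    lower 99% confidence bound of the observed mean; estimates are clipped
    to [0, 1].
    """
    b = _as_bits(bits)
    if b.size < 20:
        raise ValueError("need at least 20 bits")
    t = _collision_times(b)
    v = t.size
    if v < 2:
        raise ValueError("too few collisions to estimate")
    x_bar = float(t.mean())
    sigma = float(t.std(ddof=1))
    x_lo = x_bar - _Z99 * sigma / math.sqrt(v)
    if x_lo >= 2.5:
        return 1.0  # no solution on the curve: assess at full entropy
    pq = max((x_lo - 2.0) / 2.0, 0.0)
    p = 0.5 * (1.0 + math.sqrt(max(1.0 - 4.0 * pq, 0.0)))
    return float(min(1.0, max(0.0, -math.log2(p))))


def _markov_max_path_prob(p_init: np.ndarray, p_trans: np.ndarray, length: int) -> float:
    """Log2-probability of the most likely length-``length`` state path.

    Dynamic programme over the two states; probabilities may exceed a
    proper distribution (they are upper confidence bounds)."""
    with np.errstate(divide="ignore"):
        logp = np.log2(p_init)
        log_t = np.log2(p_trans)
    for _ in range(length - 1):
        logp = np.max(logp[:, None] + log_t, axis=0)
    return float(np.max(logp))


def markov_estimate_binary(bits) -> float:
    """First-order Markov estimate with confidence-adjusted probabilities.

    Builds upper confidence bounds on the initial and transition
    probabilities and takes the most likely 128-bit path; the estimate is
    ``−log2(p_max)/128`` clipped to [0, 1]."""
    b = _as_bits(bits)
    n = b.size
    if n < 2:
        raise ValueError("need at least 2 bits")
    n1 = int(np.count_nonzero(b))
    p_init = np.array(
        [_upper_bound((n - n1) / n, n) if n - n1 else 0.0,
         _upper_bound(n1 / n, n) if n1 else 0.0]
    )
    prev, nxt = b[:-1], b[1:]
    p_trans = np.zeros((2, 2))
    for s in (0, 1):
        mask = prev == s
        ns = int(np.count_nonzero(mask))
        if ns == 0:
            p_trans[s] = 1.0  # unreachable state: vacuous bound
            continue
        n_s1 = int(np.count_nonzero(nxt[mask]))
        for d, cnt in ((0, ns - n_s1), (1, n_s1)):
            p_trans[s, d] = _upper_bound(cnt / ns, ns) if cnt else 0.0
    logp = _markov_max_path_prob(p_init, p_trans, _PATH_LEN)
    return float(min(1.0, max(0.0, -logp / _PATH_LEN)))


def assess(bits) -> MinEntropyReport:
    """Run all three estimators; the overall figure is their minimum."""
    b = _as_bits(bits)
    if b.size < 10_000:
        warnings.warn(
            f"min-entropy assessment on only {b.size} bits; "
            "estimates are unreliable below ~10^4 bits",
            stacklevel=2,
        )
    return MinEntropyReport(
        mcv=mcv_estimate(b),
        collision=collision_estimate(b),
        markov=markov_estimate_binary(b),
    )


@dataclass
class RestartMatrix:
    """r × c matrix of bits; row i holds the first c outputs after restart i."""

    rows: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.rows, dtype=np.uint8)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("restart matrix must be at least 2 x 2")
        if m.size and m.max() > 1:
            raise ValueError("restart matrix entries must be 0/1")
        self.rows = m


@dataclass(frozen=True)
class RestartResult:
    passed: bool
    baseline: float
    row_estimate: float
    column_estimate: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "passed": self.passed,
            "baseline": self.baseline,
            "row_estimate": self.row_estimate,
            "column_estimate": self.column_estimate,
            "threshold": self.threshold,
        }


def restart_check(matrix: RestartMatrix, min_baseline: float = 0.01) -> RestartResult:
    """Restart sanity check, simplified from SP 800-90B.

    Assesses the matrix read in row order and in column order; the check
    fails when either order's overall estimate drops below half the
    row-major baseline (correlated restarts collapse the column-order
    Markov estimate), or when the baseline itself is ≈ 0.
    """
    m = matrix.rows
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        baseline = assess(m.ravel(order="C")).overall
        row_est = assess(m.ravel(order="C")).overall
        col_est = assess(m.ravel(order="F")).overall
    threshold = baseline / 2.0
    passed = baseline >= min_baseline and row_est >= threshold and col_est >= threshold
    return RestartResult(
        passed=bool(passed),
        baseline=baseline,
        row_estimate=row_est,
        column_estimate=col_est,
        threshold=threshold,
    )
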