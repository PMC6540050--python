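"""Signal cleaning ahead of entropy extraction: down-sample, then low-pass.

The pipeline order is fixed — resample to the working rate first (128 Hz by
default), then apply the low-pass filter at that rate.  Note the default
60 Hz cutoff sits just below the 64 Hz Nyquist frequency of a 128 Hz
signal, so the filter is close to all-pass there; both the cutoff and the
filter order are configurable.
"""

from __future__ import annotations

from dataclasses import replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import GSRRecord

__all__ = ["resample_to", "lowpass_filter", "preprocess"]

DEFAULT_TARGET_FS = 128.0
DEFAULT_CUTOFF_HZ = 60.0
DEFAULT_FILTER_ORDER = 4


def _ratio(target_fs: float, original_fs: float) -> Fraction:
    return (
        Fraction(target_fs).limit_denominator(10**6)
        / Fraction(original_fs).limit_denominator(10**6)
    )


def resample_to(record: GSRRecord, target_fs: float = DEFAULT_TARGET_FS) -> GSRRecord:
    """Down-sample a record to ``target_fs`` with polyphase anti-aliased
    rational resampling.

    The output length is ``ceil(n * up / down)`` for the reduced rational
    ratio ``up/down = target_fs / original_fs`` (the scipy ``resample_poly``
    contract).  Up-sampling is refused: the acquisition rates are always at
    or above the 128 Hz working rate.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if record.sampling_rate_hz < target_fs:
        raise ValueError(
            f"refusing to up-sample: record at {record.sampling_rate_hz} Hz, "
            f"target {target_fs} Hz"
        )
    if record.sampling_rate_hz == target_fs:
        return replace(record, samples=record.samples.copy())
    if len(record) < 8:
        raise ValueError("record too short to resample (need >= 8 samples)")
    frac = _ratio(target_fs, record.sampling_rate_hz)
    # padtype="line" extends the edges along a straight line, suppressing
    # the boundary transient of the anti-aliasing FIR (DC stays DC)
    out = sps.resample_poly(
        record.samples, frac.numerator, frac.denominator, padtype="line"
    )
    return GSRRecord(
        subject_id=record.subject_id,
        sampling_rate_hz=float(target_fs),
        samples=out,
        meta=dict(record.meta),
    )


def lowpass_filter(
    record: GSRRecord,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> GSRRecord:
    """Zero-phase Butterworth low-pass (forward–backward, so no group delay).

    Zero-phase filtering matters here because the downstream Hilbert step is
    phase-sensitive.  ``cutoff_hz`` must sit strictly below Nyquist.
    """
    nyq = record.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=record.sampling_rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, record.samples)
    return GSRRecord(
        subject_id=record.subject_id,
        sampling_rate_hz=record.sampling_rate_hz,
        samples=out,
        meta=dict(record.meta),
    )


def preprocess(
    record: GSRRecord,
    target_fs: float = DEFAULT_TARGET_FS,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> GSRRecord:
    """Full cleaning stage: resample to the working rate, then low-pass."""
    return lowpass_filter(resample_to(record, target_fs), cutoff_hz, order)
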