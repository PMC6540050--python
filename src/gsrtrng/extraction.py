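"""The TRNG core: window the cleaned signal, Hilbert-transform each window,
digitise the transform values into bytes.

Each non-overlapping window of ``window_seconds`` (default 4 s) is mapped
through the discrete analytic signal; the imaginary part (the Hilbert
transform of the window) is scaled, cast to an unsigned 32-bit integer and
reduced to one byte per sample.  One byte per retained sample means the
generator emits ``8 × fs`` bits per second of signal — 1024 bit/s at the
128 Hz working rate.

Two digitiser conventions are supported:

``lsb`` (default)
    byte = ``u mod 256`` — the least-significant byte, where the sensor /
    quantisation noise lives.
``shift24``
    byte = ``u >> 24`` — the literal most-significant-byte form; with a
    small scale factor this degenerates to all-zero output and is kept only
    for reproducing that behaviour.

The scale factor defaults to ``1e6`` (six decimal places of the μS value
are promoted into the integer before the byte is taken); ``1e2`` remains
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import ByteStream, GSRRecord

__all__ = [
    "DigitiserConfig",
    "WindowSet",
    "split_windows",
    "analytic_imag",
    "digitise_values",
    "generate_bytes",
]

# tolerance (in integer count units) absorbing the binary representation
# error of decimal inputs before truncation, so e.g. 1.234567 * 1e6 ->
# 1234567 rather than 1234566
_TRUNC_EPS = 1e-6


@dataclass(frozen=True)
class DigitiserConfig:
    """Parameters of the byte-extraction stage.

    window_seconds : length of the analysis window (s), default 4.
    scale_factor : multiplier promoting the Hilbert values to integers,
        default 1e6 (six decimal places).
    byte_mode : ``"lsb"`` or ``"shift24"`` (see module docstring).
    rounding : ``"truncate"`` (C-style cast) or ``"nearest"``.
    """

    window_seconds: float = 4.0
    scale_factor: float = 1e6
    byte_mode: str = "lsb"
    rounding: str = "truncate"

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.byte_mode not in ("lsb", "shift24"):
            raise ValueError(f"unknown byte_mode {self.byte_mode!r}")
        if self.rounding not in ("truncate", "nearest"):
            raise ValueError(f"unknown rounding {self.rounding!r}")


@dataclass
class WindowSet:
    """Consecutive non-overlapping equal-length windows of a record."""

    windows: np.ndarray  # shape (n_windows, samples_per_window)
    samples_per_window: int
    discarded_tail: int

    def __len__(self) -> int:
        return self.windows.shape[0]


def split_windows(record: GSRRecord, window_seconds: float = 4.0) -> WindowSet:
    """Split a record into N-second windows, discarding the partial tail."""
    spw = int(round(window_seconds * record.sampling_rate_hz))
    if spw < 8:
        raise ValueError(
            f"window of {window_seconds}s at {record.sampling_rate_hz} Hz has "
            f"{spw} samples; need >= 8"
        )
    n = len(record)
    if n < spw:
        raise ValueError(
            f"record of {n} samples shorter than one {spw}-sample window"
        )
    n_win = n // spw
    tail = n - n_win * spw
    windows = record.samples[: n_win * spw].reshape(n_win, spw)
    return WindowSet(windows=windows, samples_per_window=spw, discarded_tail=tail)


def analytic_imag(window: np.ndarray) -> np.ndarray:
    """Imaginary part of the discrete analytic signal (the Hilbert transform).

    The analytic signal's real part is the input itself; its imaginary part
    is the input with every positive-frequency component phase-shifted by
    −90°.  Computed per window with the FFT method, no tapering.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim not in (1, 2):
        raise ValueError("window must be 1-D or 2-D (batch of windows)")
    if window.shape[-1] < 8:
        raise ValueError("window length must be >= 8")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    return np.imag(sps.hilbert(window, axis=-1))


def digitise_values(values: np.ndarray, config: DigitiserConfig = DigitiserConfig()) -> ByteStream:
    """Map real values to bytes: ``u = uint32(|v| * scale)`` then take the
    configured byte (LSB or ``u >> 24``), one byte per value."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("values contain non-finite entries")
    x = np.abs(values) * config.scale_factor
    if config.rounding == "truncate":
        u = np.floor(x + _TRUNC_EPS)
    else:
        u = np.rint(x)
    u = np.mod(u, 2.0**32).astype(np.uint64)  # unsigned 32-bit cast semantics
    if config.byte_mode == "lsb":
        byte = (u & np.uint64(0xFF)).astype(np.uint8)
    else:
        byte = ((u >> np.uint64(24)) & np.uint64(0xFF)).astype(np.uint8)
    return ByteStream(byte)


def generate_bytes(record: GSRRecord, config: DigitiserConfig = DigitiserConfig()) -> ByteStream:
    """Run the full extraction on a pre-processed record.

    Windows are digitised in time order; the byte count equals the number of
    windowed samples (the partial tail is discarded), so throughput is
    exactly ``8 × fs`` bits per second of retained signal.
    """
    ws = split_windows(record, config.window_seconds)
    y = analytic_imag(ws.windows)  # batch Hilbert, one FFT per window row
    return digitise_values(y.ravel(), config)
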