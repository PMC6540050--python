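"""Reading and writing skin-conductance signals, bitstreams and PGM images.

Signals travel as :class:`GSRRecord` (samples in microsiemens plus a
sampling rate); generator output travels as :class:`ByteStream`.  Bit
serialisation is always most-significant-bit first within each byte; the
convention is fixed, not configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "GSRRecord",
    "ByteStream",
    "read_signal_csv",
    "write_signal_csv",
    "read_bits",
    "write_bits",
    "read_pgm",
    "write_pgm",
]


@dataclass
class GSRRecord:
    """A sampled skin-conductance signal.

    Parameters
    ----------
    subject_id : str
        Free-text label for the subject / recording.
    sampling_rate_hz : float
        Sampling rate in Hz; must be positive.
    samples : numpy.ndarray
        Conductance samples in microsiemens (μS); finite, length ≥ 1.
    meta : dict
        Free key–value metadata (simulation parameters, provenance, ...).
    """

    subject_id: str
    sampling_rate_hz: float
    samples: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate_hz <= 0:
            raise ValueError(
                f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}"
            )
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class ByteStream:
    """An ordered sequence of bytes with a fixed MSB-first bit convention."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 1:
            raise ValueError("byte data must be 1-D")
        if arr.dtype != np.uint8:
            if arr.size and (arr.min() < 0 or arr.max() > 255):
                raise ValueError("byte values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.data = arr

    def __len__(self) -> int:
        return self.data.size

    def to_bits(self) -> np.ndarray:
        """Serialise to a 0/1 array, MSB first within each byte."""
        return np.unpackbits(self.data)

    @classmethod
    def from_bits(cls, bits: np.ndarray) -> "ByteStream":
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.size % 8:
            raise ValueError(
                f"bit length {bits.size} is not a multiple of 8"
            )
        return cls(np.packbits(bits))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ByteStream):
            return NotImplemented
        return np.array_equal(self.data, other.data)


# ---------------------------------------------------------------------------
# signal CSV

def read_signal_csv(path, sampling_rate_hz: float, subject_id: str | None = None) -> GSRRecord:
    """Read a single-column conductance CSV into a :class:`GSRRecord`.

    The file holds one conductance value (μS) per line; an optional leading
    time column is ignored (timing comes from ``sampling_rate_hz``).  A
    non-numeric header row is auto-detected and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            cell = row[-1].strip()  # last column = conductance
            try:
                values.append(float(cell))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"non-numeric value {cell!r} on row {lineno} of {path}"
                ) from None
    if not values:
        raise ValueError(f"no numeric samples found in {path}")
    return GSRRecord(
        subject_id=subject_id or path.stem,
        sampling_rate_hz=sampling_rate_hz,
        samples=np.array(values),
    )


def write_signal_csv(record: GSRRecord, path) -> None:
    """Write one sample per line at full round-trippable precision."""
    if len(record) < 1:
        raise ValueError("record must contain at least one sample")
    with open(path, "w") as fh:
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# bitstreams

_BIT_FORMATS = ("raw", "ascii01")


def write_bits(stream: ByteStream, path, format: str = "raw") -> None:
    """Write a byte stream as raw bytes or as ASCII '0'/'1' characters.

    The ``ascii01`` form is MSB-first within each byte with no separators —
    the layout consumed by the external SP 800-22 / DIEHARDER suites.
    """
    if format not in _BIT_FORMATS:
        raise ValueError(f"unknown bitstream format {format!r}; choose from {_BIT_FORMATS}")
    if len(stream) == 0:
        raise ValueError("refusing to write an empty byte stream")
    if format == "raw":
        Path(path).write_bytes(stream.data.tobytes())
    else:
        bits = stream.to_bits()
        Path(path).write_text("".join("1" if b else "0" for b in bits))


def read_bits(path, format: str = "raw") -> ByteStream:
    """Inverse of :func:`write_bits`."""
    if format not in _BIT_FORMATS:
        raise ValueError(f"unknown bitstream format {format!r}; choose from {_BIT_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"bitstream file not found: {path}")
    if format == "raw":
        return ByteStream(np.frombuffer(path.read_bytes(), dtype=np.uint8).copy())
    text = path.read_text().strip()
    bad = set(text) - {"0", "1"}
    if bad:
        raise ValueError(f"ascii01 stream contains non-bit characters: {sorted(bad)}")
    if len(text) % 8:
        raise ValueError(f"ascii01 length {len(text)} is not a multiple of 8")
    bits = np.frombuffer(text.encode(), dtype=np.uint8) - ord("0")
    return ByteStream.from_bits(bits)


# ---------------------------------------------------------------------------
# PGM (binary, "P5")

def write_pgm(stream: ByteStream, width: int, height: int, path) -> None:
    """Render the first ``width × height`` bytes as a binary 8-bit PGM image.

    This is the visual-inspection export: a strong generator's bytes render
    as featureless grey noise.
    """
    need = width * height
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    if len(stream) < need:
        raise ValueError(
            f"need {need} bytes for a {width}x{height} image, have {len(stream)}"
        )
    header = f"P5\n{width} {height}\n255\n".encode()
    Path(path).write_bytes(header + stream.data[:need].tobytes())


def read_pgm(path) -> tuple[int, int, np.ndarray]:
    """Read a binary P5 PGM; returns (width, height, row-major uint8 pixels)."""
    raw = Path(path).read_bytes()
    # header: magic, width, height, maxval — whitespace separated
    tokens: list[bytes] = []
    i = 0
    while len(tokens) < 4:
        while i < len(raw) and raw[i : i + 1].isspace():
            i += 1
        if raw[i : i + 1] == b"#":  # comment line
            while i < len(raw) and raw[i] != 0x0A:
                i += 1
            continue
        j = i
        while j < len(raw) and not raw[j : j + 1].isspace():
            j += 1
        tokens.append(raw[i:j])
        i = j
    if tokens[0] != b"P5":
        raise ValueError("not a binary (P5) PGM file")
    width, height, maxval = (int(t) for t in tokens[1:])
    if maxval != 255:
        raise ValueError(f"only 8-bit PGM supported (maxval 255), got {maxval}")
    pixels = np.frombuffer(raw[i + 1 : i + 1 + width * height], dtype=np.uint8).copy()
    if pixels.size != width * height:
        raise ValueError("PGM pixel payload shorter than header promises")
    return width, height, pixels
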