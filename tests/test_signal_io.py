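import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gsrtrng.signal_io import (
    ByteStream,
    GSRRecord,
    read_bits,
    read_pgm,
    read_signal_csv,
    write_bits,
    write_pgm,
    write_signal_csv,
)

byte_lists = st.lists(st.integers(0, 255), min_size=1, max_size=64)


class TestGSRRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GSRRecord("s", -1.0, [1.0])
        with pytest.raises(ValueError):
            GSRRecord("s", 128.0, [])
        with pytest.raises(ValueError):
            GSRRecord("s", 128.0, [1.0, np.nan])

    def test_duration(self):
        rec = GSRRecord("s", 128.0, np.zeros(256))
        assert rec.duration_s == 2.0


class TestSignalCsv:
    def test_plain_parse(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("1.0\n1.1\n1.2\n")
        rec = read_signal_csv(p, sampling_rate_hz=128)
        assert rec.sampling_rate_hz == 128
        np.testing.assert_array_equal(rec.samples, [1.0, 1.1, 1.2])

    def test_header_and_time_column_ignored(self, tmp_path):
        p = tmp_path / "sig.csv"
        p.write_text("time,conductance\n0.0,1.5\n0.0078,1.6\n")
        rec = read_signal_csv(p, sampling_rate_hz=128)
        np.testing.assert_array_equal(rec.samples, [1.5, 1.6])

    def test_round_trip(self, tmp_path, rng):
        rec = GSRRecord("s", 128.0, rng.normal(2, 0.1, 100))
        p = tmp_path / "rt.csv"
        write_signal_csv(rec, p)
        back = read_signal_csv(p, sampling_rate_hz=128)
        np.testing.assert_array_equal(back.samples, rec.samples)

    def test_bad_row_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1.0\nabc\n1.2\n")
        with pytest.raises(ValueError, match="row 2"):
            read_signal_csv(p, sampling_rate_hz=128)

    def test_missing_and_empty_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_signal_csv(tmp_path / "nope.csv", 128)
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="no numeric samples"):
            read_signal_csv(p, 128)

    def test_single_sample_write(self, tmp_path):
        p = tmp_path / "one.csv"
        write_signal_csv(GSRRecord("s", 128.0, [0.0]), p)
        assert p.read_text() == "0.0\n"


class TestBitstreams:
    def test_ascii01_msb_first(self, tmp_path):
        p = tmp_path / "b.txt"
        write_bits(ByteStream(np.array([1], dtype=np.uint8)), p, format="ascii01")
        assert p.read_text() == "00000001"
        write_bits(ByteStream(np.array([255, 0], dtype=np.uint8)), p, format="ascii01")
        assert p.read_text() == "1111111100000000"

    def test_raw_verbatim(self, tmp_path):
        p = tmp_path / "b.raw"
        write_bits(ByteStream(np.array([171], dtype=np.uint8)), p, format="raw")
        assert p.read_bytes() == b"\xab"

    def test_ascii01_read(self, tmp_path):
        p = tmp_path / "b.txt"
        p.write_text("00000001")
        assert read_bits(p, format="ascii01").data.tolist() == [1]

    @pytest.mark.parametrize("fmt", ["raw", "ascii01"])
    @given(data=byte_lists)
    def test_round_trip_identity(self, tmp_path, fmt, data):
        stream = ByteStream(np.array(data, dtype=np.uint8))
        p = tmp_path / f"rt.{fmt}"
        write_bits(stream, p, format=fmt)
        assert read_bits(p, format=fmt) == stream

    @given(data=byte_lists)
    def test_ascii01_length_and_bit_counts(self, tmp_path, data):
        stream = ByteStream(np.array(data, dtype=np.uint8))
        p = tmp_path / "c.txt"
        write_bits(stream, p, format="ascii01")
        text = p.read_text()
        assert len(text) == 8 * len(data)
        assert text.count("1") == int(np.unpackbits(stream.data).sum())

    def test_errors(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0000001")  # 7 chars
        with pytest.raises(ValueError, match="multiple of 8"):
            read_bits(p, format="ascii01")
        p.write_text("0000000x")
        with pytest.raises(ValueError, match="non-bit"):
            read_bits(p, format="ascii01")
        with pytest.raises(ValueError, match="format"):
            write_bits(ByteStream(np.array([1], dtype=np.uint8)), p, format="hex")
        with pytest.raises(ValueError, match="empty"):
            write_bits(ByteStream(np.array([], dtype=np.uint8)), p, format="raw")


class TestPgm:
    def test_header_and_payload(self, tmp_path):
        p = tmp_path / "img.pgm"
        write_pgm(ByteStream(np.array([1, 2, 3, 4], dtype=np.uint8)), 2, 2, p)
        assert p.read_bytes() == b"P5\n2 2\n255\n\x01\x02\x03\x04"

    def test_round_trip(self, tmp_path, rng):
        data = ByteStream(rng.integers(0, 256, 512 * 512, dtype=np.uint8))
        p = tmp_path / "big.pgm"
        write_pgm(data, 512, 512, p)
        w, h, px = read_pgm(p)
        assert (w, h) == (512, 512)
        np.testing.assert_array_equal(px, data.data)

    def test_insufficient_bytes(self, tmp_path):
        with pytest.raises(ValueError, match="4 bytes"):
            write_pgm(ByteStream(np.array([1, 2, 3], dtype=np.uint8)), 2, 2, tmp_path / "x.pgm")


class TestByteStream:
    def test_bit_serialisation_length(self):
        s = ByteStream(np.array([7, 8, 9], dtype=np.uint8))
        assert s.to_bits().size == 24
        assert ByteStream.from_bits(s.to_bits()) == s

    def test_value_range_checked(self):
        with pytest.raises(ValueError):
            ByteStream(np.array([256]))
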