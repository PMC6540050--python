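import numpy as np
import pytest

from gsrtrng.ent import byte_entropy
from gsrtrng.extraction import (
    DigitiserConfig,
    analytic_imag,
    digitise_values,
    generate_bytes,
    split_windows,
)
from gsrtrng.preprocess import preprocess
from gsrtrng.signal_io import GSRRecord
from gsrtrng.synthetic import SimConfig, simulate_record


class TestSplitWindows:
    def test_window_arithmetic(self):
        rec = GSRRecord("s", 128.0, np.zeros(1280))
        ws = split_windows(rec, 4.0)
        assert len(ws) == 2
        assert ws.samples_per_window == 512
        assert ws.discarded_tail == 256

    def test_exact_fit(self):
        ws = split_windows(GSRRecord("s", 128.0, np.zeros(512)), 4.0)
        assert len(ws) == 1 and ws.discarded_tail == 0

    def test_too_short(self):
        with pytest.raises(ValueError, match="shorter"):
            split_windows(GSRRecord("s", 128.0, np.zeros(511)), 4.0)

    def test_windows_are_consecutive(self):
        rec = GSRRecord("s", 128.0, np.arange(1024, dtype=float))
        ws = split_windows(rec, 4.0)
        np.testing.assert_array_equal(ws.windows.ravel(), np.arange(1024))


class TestAnalyticImag:
    def test_zero_in_zero_out(self):
        assert np.all(analytic_imag(np.zeros(512)) == 0)

    def test_cosine_becomes_sine(self):
        """A −90° phase shift turns cos into sin; 8 Hz over a 4 s window is
        an integer number of cycles so even the edges are clean."""
        t = np.arange(512) / 128.0
        y = analytic_imag(np.cos(2 * np.pi * 8 * t))
        interior = slice(128, 384)
        assert np.max(np.abs(y[interior] - np.sin(2 * np.pi * 8 * t)[interior])) < 0.05

    def test_linearity(self):
        t = np.arange(512) / 128.0
        a = np.cos(2 * np.pi * 8 * t)
        b = np.cos(2 * np.pi * 16 * t)
        np.testing.assert_allclose(
            analytic_imag(a + b), analytic_imag(a) + analytic_imag(b), atol=1e-10
        )

    def test_analytic_real_part_reproduces_input(self, rng):
        from scipy.signal import hilbert

        x = rng.normal(0, 1, 512)
        assert np.max(np.abs(np.real(hilbert(x)) - x)) < 1e-9

    def test_non_finite_rejected(self):
        bad = np.zeros(64)
        bad[3] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            analytic_imag(bad)


class TestDigitise:
    def test_zero_maps_to_zero(self):
        for mode in ("lsb", "shift24"):
            cfg = DigitiserConfig(byte_mode=mode)
            assert digitise_values([0.0], cfg).data.tolist() == [0]

    def test_lsb_integer_oracle(self):
        # 1.234567 * 1e6 = 1234567; 1234567 mod 256 = 135
        out = digitise_values([1.234567], DigitiserConfig(scale_factor=1e6))
        assert out.data.tolist() == [135]

    def test_literal_constants_degenerate(self):
        # 1.234567 * 100 = 123 (truncated); 123 >> 24 = 0
        cfg = DigitiserConfig(scale_factor=100, byte_mode="shift24")
        assert digitise_values([1.234567], cfg).data.tolist() == [0]

    def test_nearest_rounding(self):
        cfg = DigitiserConfig(scale_factor=1e6, rounding="nearest")
        assert digitise_values([1.2345678], cfg).data.tolist() == [(1234568) % 256]

    def test_sign_ignored(self):
        cfg = DigitiserConfig()
        assert digitise_values([-1.234567], cfg) == digitise_values([1.234567], cfg)

    def test_wraps_modulo_2_32(self):
        # 2^32 + 5 counts wraps to 5
        v = (2**32 + 5) / 1e6
        out = digitise_values([v], DigitiserConfig(scale_factor=1e6))
        assert out.data.tolist() == [5]


class TestGenerateBytes:
    def test_throughput_contract(self, rng):
        """8 s at 128 Hz → two 4-s windows → 1024 bytes = 8192 bits,
        i.e. 1024 bits per second of signal."""
        rec = GSRRecord("s", 128.0, rng.normal(2, 0.1, 1024))
        stream = generate_bytes(rec)
        assert len(stream) == 1024
        assert 8 * len(stream) / rec.duration_s == 1024

    def test_all_zero_record(self):
        rec = GSRRecord("s", 128.0, np.zeros(1024))
        stream = generate_bytes(rec)
        assert len(stream) == 1024
        assert np.all(stream.data == 0)

    def test_determinism(self, rng):
        rec = GSRRecord("s", 128.0, rng.normal(2, 0.1, 2048))
        assert generate_bytes(rec) == generate_bytes(rec)

    def test_lsb_beats_literal_shift24_on_noisy_gsr(self):
        """With the literal printed constants (scale 100, >>24) μS-scale
        values digitise to all-zero bytes; the LSB mode harvests the noise."""
        rec = simulate_record(SimConfig(duration_s=64, noise_sd_us=0.1, seed=9))
        clean = preprocess(rec)
        h_lsb = byte_entropy(generate_bytes(clean, DigitiserConfig()))
        h_lit = byte_entropy(
            generate_bytes(clean, DigitiserConfig(scale_factor=100, byte_mode="shift24"))
        )
        assert h_lsb > h_lit
        assert h_lsb > 7.0

    def test_matches_manual_window_pipeline(self, rng):
        rec = GSRRecord("s", 128.0, rng.normal(2, 0.1, 1536))
        cfg = DigitiserConfig()
        ws = split_windows(rec, cfg.window_seconds)
        manual = np.concatenate(
            [digitise_values(analytic_imag(w), cfg).data for w in ws.windows]
        )
        np.testing.assert_array_equal(generate_bytes(rec, cfg).data, manual)
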