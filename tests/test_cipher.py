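import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gsrtrng.cipher import (
    GrayImage,
    diffusion_experiment,
    npcr,
    npcr_critical,
    uaci,
    uaci_bounds,
    xor_encrypt,
)
from gsrtrng.ent import chi_square_bytes
from gsrtrng.signal_io import ByteStream


@pytest.fixture()
def image(rng):
    # structured plaintext: smooth gradient, decidedly non-uniform histogram
    g = np.add.outer(np.arange(256), np.arange(256)) // 2
    return GrayImage(256, 256, g.astype(np.uint8))


def keystream_for(seed, n=65536):
    return ByteStream(np.random.default_rng(seed).integers(0, 256, n, dtype=np.uint8))


class TestXorEncrypt:
    def test_zero_keystream_is_identity(self, image):
        zero = ByteStream(np.zeros(65536, dtype=np.uint8))
        assert np.array_equal(xor_encrypt(image, zero).pixels, image.pixels)

    def test_involution(self, image):
        ks = keystream_for(1)
        assert np.array_equal(xor_encrypt(xor_encrypt(image, ks), ks).pixels, image.pixels)

    def test_uniform_keystream_flattens_histogram(self, image):
        """XOR with uniform bytes makes the ciphertext histogram uniform:
        its χ² lands in the central 99% of χ²₂₅₅."""
        from scipy.stats import chi2

        cipher = xor_encrypt(image, keystream_for(2))
        stat, _ = chi_square_bytes(ByteStream(cipher.pixels))
        lo, hi = chi2.ppf([0.005, 0.995], 255)
        assert lo < stat < hi

    def test_keystream_too_short(self, image):
        with pytest.raises(ValueError, match="keystream"):
            xor_encrypt(image, ByteStream(np.zeros(100, dtype=np.uint8)))


class TestNpcrUaci:
    def test_identical_images(self, image):
        assert npcr(image, image) == 0.0
        assert uaci(image, image) == 0.0

    def test_single_differing_pixel(self, image):
        other = GrayImage(256, 256, image.pixels.copy())
        other.pixels[0] ^= 1
        assert npcr(image, other) == pytest.approx(100 / 65536)

    def test_every_pixel_shifted(self, image):
        shifted = GrayImage(256, 256, (image.pixels.astype(np.int16) + 1) % 256)
        assert npcr(image, shifted) == 100.0

    def test_unit_intensity_change(self, image):
        up = GrayImage(256, 256, np.where(image.pixels < 255, image.pixels + 1, 254))
        assert uaci(image, up) == pytest.approx(100 / 255)

    def test_full_scale_change(self):
        black = GrayImage(16, 16, np.zeros(256, dtype=np.uint8))
        white = GrayImage(16, 16, np.full(256, 255, dtype=np.uint8))
        assert uaci(black, white) == 100.0
        assert npcr(black, white) == 100.0

    @given(st.integers(0, 2**16))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = GrayImage(8, 8, rng.integers(0, 256, 64, dtype=np.uint8))
        b = GrayImage(8, 8, rng.integers(0, 256, 64, dtype=np.uint8))
        assert npcr(a, b) == npcr(b, a)
        assert uaci(a, b) == uaci(b, a)

    def test_dimension_mismatch(self, image):
        small = GrayImage(8, 8, np.zeros(64, dtype=np.uint8))
        with pytest.raises(ValueError):
            npcr(image, small)


class TestThresholds:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.05, 99.5693), (0.01, 99.5527), (0.001, 99.5341)],
    )
    def test_npcr_critical_printed_values(self, alpha, expected):
        assert round(npcr_critical(alpha, 255, 65536), 4) == expected

    def test_uaci_bounds_printed_values(self):
        lo, hi = uaci_bounds(0.05, 255, 65536)
        assert (round(lo, 4), round(hi, 4)) == (33.2824, 33.6447)

    def test_limits(self):
        # n → ∞: NPCR → 100·F/(F+1), UACI band collapses onto the mean
        assert npcr_critical(0.05, 255, 10**15) == pytest.approx(100 * 255 / 256, abs=1e-4)
        lo, hi = uaci_bounds(0.05, 255, 10**15)
        mu = 100 * 257 / 768
        assert lo == pytest.approx(mu, abs=1e-4)
        assert hi == pytest.approx(mu, abs=1e-4)

    def test_monotonicity(self):
        assert npcr_critical(0.01) < npcr_critical(0.05)
        w_small = np.diff(uaci_bounds(0.05, 255, 65536))[0]
        w_big = np.diff(uaci_bounds(0.05, 255, 4 * 65536))[0]
        assert w_big < w_small


class TestDiffusionExperiment:
    def test_shared_keystream_has_no_diffusion(self, image):
        """Under one shared keystream a single flipped plaintext bit changes
        exactly one ciphertext pixel — NPCR ≈ 0.0015%, far below threshold."""
        result = diffusion_experiment(image, keystream_for(3), alpha=0.05)
        assert result.npcr_pct == pytest.approx(100 / 65536)
        assert not result.npcr_pass

    def test_independent_keystreams_reach_pass_region(self, image):
        passes = 0
        for seed in range(100):
            r = np.random.default_rng(20_000 + seed)
            k1 = ByteStream(r.integers(0, 256, 65536, dtype=np.uint8))
            k2 = ByteStream(r.integers(0, 256, 65536, dtype=np.uint8))
            result = diffusion_experiment(image, k1, alpha=0.05, keystream2=k2)
            passes += result.npcr_pass
        assert passes >= 95

    def test_same_plaintext_same_keystream_unchanged(self, image):
        ks = keystream_for(5)
        c1 = xor_encrypt(image, ks)
        c2 = xor_encrypt(image, ks)
        assert npcr(c1, c2) == 0.0
        assert uaci(c1, c2) == 0.0
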