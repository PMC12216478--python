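"""Block-scrambling cipher: key derivation, the four steps, exact inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermpipe import crypto
from dermpipe.image import RasterImage, load_image, save_image


# ----------------------------------------------------------------- derive_keys
class TestDeriveKeys:
    def test_singleton_permutation(self):
        keys = crypto.derive_keys(0, 1)
        assert list(keys.k1) == [0]

    def test_deterministic(self):
        a = crypto.derive_keys(99, 64)
        b = crypto.derive_keys(99, 64)
        for stream in ("k1", "k2", "k3", "k4"):
            assert np.array_equal(getattr(a, stream), getattr(b, stream))

    def test_streams_sized_and_ranged(self):
        keys = crypto.derive_keys(5, 100)
        assert sorted(keys.k1) == list(range(100))  # bijection
        assert keys.k2.min() >= 0 and keys.k2.max() <= 7
        assert set(np.unique(keys.k3)) <= {0, 1}
        assert keys.k4.min() >= 0 and keys.k4.max() <= 5

    def test_negpos_bit_frequency_near_half(self):
        # binomial bound: at n=1e4 the frequency of r(i)=1 is 0.5 +/- 0.02
        keys = crypto.derive_keys(7, 10_000)
        assert abs(keys.k3.mean() - 0.5) < 0.02

    @pytest.mark.parametrize("bad", [0, -3])
    def test_invalid_block_count(self, bad):
        with pytest.raises(ValueError):
            crypto.derive_keys(0, bad)


# ------------------------------------------------------------------- partition
class TestPartition:
    def test_2x2_grid(self, random_rgb):
        part, blocks = crypto.partition_image(random_rgb(32, 32), 16, 16)
        assert part.n_blocks == len(blocks) == 4

    def test_sample_setting_256_blocks(self, random_rgb):
        part, _ = crypto.partition_image(random_rgb(256, 256), 16, 16)
        assert part.n_blocks == 256

    def test_partition_reassemble_identity(self, random_rgb):
        img = random_rgb(48, 80, seed=3)
        part, blocks = crypto.partition_image(img, 16, 16)
        back = crypto.assemble_image(blocks, part, img)
        assert np.array_equal(back.pixels, img.pixels)

    def test_non_divisible_error_names_axis(self, random_rgb):
        with pytest.raises(ValueError, match="height"):
            crypto.partition_image(random_rgb(30, 32), 16, 16)
        with pytest.raises(ValueError, match="width"):
            crypto.partition_image(random_rgb(32, 30), 16, 16)

    def test_padding_recorded_and_cropped(self, random_rgb):
        img = random_rgb(30, 45, seed=5)
        part, blocks = crypto.partition_image(img, 16, 16, pad=True)
        assert (part.pad_bottom, part.pad_right) == (2, 3)
        back = crypto.assemble_image(blocks, part, img)
        assert np.array_equal(back.pixels, img.pixels)


# ---------------------------------------------------------- negative-positive
class TestNegPos:
    def test_zero_maps_to_max(self):
        blk = np.zeros((4, 4), dtype=np.uint8)
        assert crypto.negpos_transform(blk, 1, 8).max() == 255

    def test_r_zero_is_identity(self, rng):
        blk = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        assert np.array_equal(crypto.negpos_transform(blk, 0, 8), blk)

    def test_xor_oracle(self):
        blk = np.full((2, 2), 100, dtype=np.uint8)
        assert crypto.negpos_transform(blk, 1, 8)[0, 0] == 100 ^ 255 == 155

    def test_involution(self, rng):
        blk = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        twice = crypto.negpos_transform(crypto.negpos_transform(blk, 1, 8), 1, 8)
        assert np.array_equal(twice, blk)

    def test_other_bit_depths(self):
        blk = np.array([[5]], dtype=np.uint16)
        assert crypto.negpos_transform(blk, 1, 12)[0, 0] == 5 ^ 4095


# -------------------------------------------------------------------- dihedral
def _rot90_oracle(block):
    n = block.shape[0]
    out = np.empty_like(block)
    for i in range(n):
        for j in range(n):
            out[i, j] = block[j, n - 1 - i]
    return out


def _fliplr_oracle(block):
    n = block.shape[1]
    out = np.empty_like(block)
    for j in range(n):
        out[:, j] = block[:, n - 1 - j]
    return out


class TestDihedral:
    def test_identity(self, rng):
        blk = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.array_equal(crypto.dihedral_transform(blk, 0), blk)

    def test_rotation_order_four(self):
        blk = np.arange(9, dtype=np.uint8).reshape(3, 3)
        out = blk
        for _ in range(4):
            out = crypto.dihedral_transform(out, 1)
        assert np.array_equal(out, blk)

    @pytest.mark.parametrize("k", range(8))
    def test_matches_index_remapping_oracle(self, k):
        blk = np.arange(9, dtype=np.int64).reshape(3, 3)  # all-distinct marks
        expected = blk
        for _ in range(k % 4):
            expected = _rot90_oracle(expected)
        if k >= 4:
            expected = _fliplr_oracle(expected)
        assert np.array_equal(crypto.dihedral_transform(blk, k), expected)

    @pytest.mark.parametrize("k", range(8))
    def test_inverse_index_restores(self, k, rng):
        blk = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        fwd = crypto.dihedral_transform(blk, k)
        back = crypto.dihedral_transform(fwd, crypto.dihedral_inverse_index(k))
        assert np.array_equal(back, blk)

    def test_preserves_pixel_multiset(self, rng):
        blk = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        for k in range(8):
            out = crypto.dihedral_transform(blk, k)
            assert sorted(out.ravel()) == sorted(blk.ravel())

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            crypto.dihedral_transform(np.zeros((4, 8), dtype=np.uint8), 1)


# ------------------------------------------------------------- channel shuffle
class TestChannelShuffle:
    def test_identity_index(self, rng):
        blk = rng.integers(0, 256, (4, 4, 3), dtype=np.uint8)
        assert np.array_equal(crypto.shuffle_channels(blk, 0), blk)

    def test_six_distinct_outputs(self):
        blk = np.zeros((2, 2, 3), dtype=np.uint8)
        blk[..., 0], blk[..., 1], blk[..., 2] = 10, 20, 30
        outs = {crypto.shuffle_channels(blk, k).tobytes() for k in range(6)}
        assert len(outs) == 6

    @pytest.mark.parametrize("k", range(6))
    def test_inverse_composition(self, k, rng):
        blk = rng.integers(0, 256, (4, 4, 3), dtype=np.uint8)
        out = crypto.shuffle_channels(
            crypto.shuffle_channels(blk, k), crypto.channel_inverse_index(k)
        )
        assert np.array_equal(out, blk)

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError, match="3-channel"):
            crypto.shuffle_channels(np.zeros((4, 4), dtype=np.uint8), 1)


# ------------------------------------------------------------ encrypt/decrypt
class TestEncryptDecrypt:
    def test_identity_keyset_is_identity(self, random_rgb):
        img = random_rgb(32, 32)
        part, _ = crypto.partition_image(img, 16, 16)
        n = part.n_blocks
        keys = crypto.KeySet(0, np.arange(n), np.zeros(n, int), np.zeros(n, int), np.zeros(n, int))
        enc = crypto.encrypt(img, keys, part)
        assert np.array_equal(enc.pixels, img.pixels)

    def test_histogram_preserved_without_negpos_and_shuffle(self, random_rgb):
        img = random_rgb(64, 64, seed=8)
        part, _ = crypto.partition_image(img, 16, 16)
        keys = crypto.derive_keys(11, part.n_blocks)
        enc = crypto.encrypt(img, keys, part, steps=(True, True, False, False))
        for ch in range(3):
            h0 = np.bincount(img.pixels[..., ch].ravel(), minlength=256)
            h1 = np.bincount(enc.pixels[..., ch].ravel(), minlength=256)
            assert np.array_equal(h0, h1)

    def test_k1_preserves_block_multiset(self, random_rgb):
        img = random_rgb(64, 64, seed=2)
        part, blocks = crypto.partition_image(img, 16, 16)
        keys = crypto.derive_keys(4, part.n_blocks)
        enc = crypto.encrypt(img, keys, part, steps=(True, False, False, False))
        _, enc_blocks = crypto.partition_image(enc, 16, 16)
        assert sorted(b.tobytes() for b in blocks) == sorted(b.tobytes() for b in enc_blocks)

    def test_shape_and_dtype_preserved(self, random_rgb):
        img = random_rgb(64, 96, seed=1)
        enc, _, _ = crypto.encrypt_image(img, 3, block_size=16)
        assert enc.pixels.shape == img.pixels.shape
        assert enc.pixels.dtype == img.pixels.dtype
        assert enc.bit_depth == img.bit_depth

    def test_roundtrip_exact(self, random_rgb):
        img = random_rgb(64, 64, seed=10)
        enc, keys, part = crypto.encrypt_image(img, 17)
        dec = crypto.decrypt(enc, keys, part)
        assert np.array_equal(dec.pixels, img.pixels)

    def test_roundtrip_sample_block_size_256(self, random_rgb):
        img = random_rgb(256, 256, seed=4)
        enc, keys, part = crypto.encrypt_image(img, 23, block_size=16)
        dec = crypto.decrypt(enc, keys, part)
        assert np.array_equal(dec.pixels, img.pixels)

    def test_wrong_seed_fails_to_recover(self, random_rgb):
        img = random_rgb(64, 64, seed=6)
        for seed in range(10):
            enc, _, part = crypto.encrypt_image(img, seed)
            wrong = crypto.derive_keys(seed + 1000, part.n_blocks)
            dec = crypto.decrypt(enc, wrong, part)
            diff = np.abs(dec.pixels.astype(int) - img.pixels.astype(int)).mean()
            assert diff > 0

    def test_key_size_mismatch(self, random_rgb):
        img = random_rgb(64, 64)
        part, _ = crypto.partition_image(img, 16, 16)
        keys = crypto.derive_keys(0, part.n_blocks + 1)
        with pytest.raises(ValueError, match="sized for"):
            crypto.encrypt(img, keys, part)

    def test_padded_roundtrip(self, random_rgb):
        img = random_rgb(50, 70, seed=9)
        enc, keys, part = crypto.encrypt_image(img, 31, pad=True)
        assert enc.pixels.shape == (64, 80, 3)
        dec = crypto.decrypt(enc, keys, part)
        assert np.array_equal(dec.pixels, img.pixels)

    def test_grayscale_roundtrip(self, rng):
        img = RasterImage(rng.integers(0, 256, (32, 32), dtype=np.uint8))
        enc, keys, part = crypto.encrypt_image(img, 5)
        dec = crypto.decrypt(enc, keys, part)
        assert np.array_equal(dec.pixels, img.pixels)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        h_blocks=st.integers(1, 4),
        w_blocks=st.integers(1, 4),
        bsz=st.sampled_from([8, 16]),
    )
    def test_roundtrip_property(self, seed, h_blocks, w_blocks, bsz):
        g = np.random.default_rng(seed)
        img = RasterImage(g.integers(0, 256, (h_blocks * bsz, w_blocks * bsz, 3), dtype=np.uint8))
        enc, keys, part = crypto.encrypt_image(img, seed, block_size=bsz)
        dec = crypto.decrypt(enc, keys, part)
        assert np.array_equal(dec.pixels, img.pixels)


# ---------------------------------------------------------------------- on-disk
class TestSerialization:
    def test_png_ciphertext_decrypts_exactly(self, random_rgb, tmp_path):
        img = random_rgb(64, 64, seed=12)
        enc, keys, part = crypto.encrypt_image(img, 77)
        path = save_image(enc, tmp_path / "cipher.png")
        reloaded = load_image(path)
        dec = crypto.decrypt(reloaded, keys, part)
        assert np.array_equal(dec.pixels, img.pixels)

    def test_jpeg_ciphertext_decodes(self, random_rgb, tmp_path):
        # JPEG is lossy: a smoke test only — the file must decode to the right
        # shape, exact decryption is not expected.
        img = random_rgb(64, 64, seed=13)
        enc, _, _ = crypto.encrypt_image(img, 78)
        path = save_image(enc, tmp_path / "cipher.jpg")
        reloaded = load_image(path)
        assert reloaded.pixels.shape == img.pixels.shape

    def test_key_manifest_roundtrip(self, tmp_path):
        p = crypto.write_key_manifest(
            tmp_path / "keys.json", master_seed=5, block_size=16, pad_bottom=2, pad_right=0
        )
        m = crypto.read_key_manifest(p)
        assert m == {"master_seed": 5, "block_size": 16, "pad_bottom": 2, "pad_right": 0}
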