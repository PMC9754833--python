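"""Degradation, patch sampling, augmentation and image I/O."""

import numpy as np
import pytest

from ctsr.data import (Image, PatchPair, SplitSpec, augment, bicubic_resize,
                       center_crop_to_multiple, degrade, dihedral_transform,
                       read_image, read_manifest, sample_patch_pair,
                       write_image, write_manifest)


def catmull_rom(x):
    x = abs(x)
    if x < 1:
        return 1.5 * x ** 3 - 2.5 * x ** 2 + 1
    if x < 2:
        return -0.5 * x ** 3 + 2.5 * x ** 2 - 4 * x + 2
    return 0.0


def resize_oracle_1d(src, out_n):
    """Separable antialiased Catmull-Rom resampling, brute-force weights."""
    in_n = len(src)
    scale = in_n / out_n
    support = 2.0 * max(scale, 1.0)
    out = np.zeros(out_n)
    for i in range(out_n):
        center = (i + 0.5) * scale
        lo = int(np.floor(center - support + 0.5))
        hi = int(np.ceil(center + support + 0.5))
        ws, vs = [], []
        for j in range(lo, hi):
            if not 0 <= j < in_n:
                continue      # out-of-range taps are dropped, not clamped
            w = catmull_rom((j + 0.5 - center) / max(scale, 1.0))
            if w != 0:
                ws.append(w)
                vs.append(src[j])
        ws = np.array(ws)
        out[i] = np.dot(ws / ws.sum(), vs)
    return out


class TestBicubicResize:
    def test_constant_preserved_any_size(self):
        img = Image(np.full((1, 17, 13), 0.37, dtype=np.float32))
        for oh, ow in ((5, 9), (17, 13), (40, 3)):
            out = bicubic_resize(img, oh, ow)
            assert out.data.shape == (1, oh, ow)
            assert np.allclose(out.data, 0.37, atol=1e-6)

    def test_identity_at_same_size(self, rng):
        img = Image(rng.random((1, 12, 12)).astype(np.float32))
        out = bicubic_resize(img, 12, 12)
        assert np.allclose(out.data, img.data, atol=1e-6)

    def test_downscale_matches_kernel_summation_oracle(self, rng):
        """Separable 1-D check: a row image downscaled by 2 must match the
        brute-force antialiased Catmull-Rom weights."""
        row = rng.random(16).astype(np.float32)
        img = Image(np.tile(row, (1, 16, 1)))
        out = bicubic_resize(img, 8, 8)
        want = resize_oracle_1d(row.astype(np.float64), 8)
        assert np.allclose(out.data[0, 4], want, atol=5e-4)

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            bicubic_resize(Image(np.zeros((1, 8, 8), dtype=np.float32)), 0, 4)


class TestDegrade:
    def test_dims_contract(self, rng):
        hr = Image(rng.random((1, 32, 48)).astype(np.float32))
        lr = degrade(hr, 2)
        assert lr.data.shape == (1, 16, 24)

    def test_equals_bicubic_resize(self, rng):
        hr = Image(rng.random((1, 32, 32)).astype(np.float32))
        assert np.array_equal(degrade(hr, 4).data,
                              bicubic_resize(hr, 8, 8).data)

    def test_crops_to_multiple_first(self, rng):
        hr = Image(rng.random((1, 33, 34)).astype(np.float32))
        lr = degrade(hr, 2)
        assert lr.data.shape == (1, 16, 17)

    def test_constant_in_constant_out(self):
        hr = Image(np.full((1, 24, 24), 0.5, dtype=np.float32))
        assert np.allclose(degrade(hr, 2).data, 0.5, atol=1e-6)


class TestPatchPair:
    def test_seeded_sampling_reproducible(self, rng):
        hr = Image(rng.random((1, 64, 64)).astype(np.float32))
        lr = degrade(hr, 2)
        a = sample_patch_pair(hr, lr, 8, 2, 42)
        b = sample_patch_pair(hr, lr, 8, 2, 42)
        assert a.top_left == b.top_left
        assert np.array_equal(a.hr.data, b.hr.data)

    def test_whole_image_patch(self, rng):
        hr = Image(rng.random((1, 32, 32)).astype(np.float32))
        lr = degrade(hr, 2)
        pair = sample_patch_pair(hr, lr, 16, 2, 0)
        assert np.array_equal(pair.lr.data, lr.data)
        assert np.array_equal(pair.hr.data, hr.data)

    def test_too_small_image_rejected(self, rng):
        hr = Image(rng.random((1, 16, 16)).astype(np.float32))
        lr = degrade(hr, 2)
        with pytest.raises(ValueError):
            sample_patch_pair(hr, lr, 12, 2, 0)

    def test_alignment_by_re_degradation(self):
        """Interior of degrade(HR patch) must equal the LR patch: the patch
        grids are aligned by construction, so only resampling boundary
        effects (kernel support 2 LR px) may differ."""
        gen = np.random.default_rng(77)
        hr = Image(gen.random((1, 96, 96)).astype(np.float32))
        lr = degrade(hr, 2)
        for trial in range(100):
            pair = sample_patch_pair(hr, lr, 16, 2, 1000 + trial)
            re = degrade(pair.hr, 2)
            inner = (slice(None), slice(3, -3), slice(3, -3))
            assert np.allclose(re.data[inner], pair.lr.data[inner], atol=1e-5)

    def test_mismatched_scale_rejected(self, rng):
        hr = Image(rng.random((1, 30, 30)).astype(np.float32))
        lr = degrade(hr, 2)
        with pytest.raises(ValueError):
            PatchPair(lr, Image(hr.data[:, :20, :20]))


class TestAugment:
    def test_deterministic_given_seed(self, rng):
        hr = Image(rng.random((1, 32, 32)).astype(np.float32))
        lr = degrade(hr, 2)
        pair = sample_patch_pair(hr, lr, 8, 2, 0)
        a, b = augment(pair, 5), augment(pair, 5)
        assert np.array_equal(a.hr.data, b.hr.data)

    def test_dihedral_group_properties(self, rng):
        x = rng.random((1, 6, 6)).astype(np.float32)
        assert np.array_equal(dihedral_transform(x, 0), x)
        outs = {dihedral_transform(x, k).tobytes() for k in range(8)}
        assert len(outs) == 8      # all 8 elements distinct on generic input

    def test_pair_stays_aligned_after_augmentation(self):
        gen = np.random.default_rng(88)
        hr = Image(gen.random((1, 64, 64)).astype(np.float32))
        lr = degrade(hr, 2)
        for trial in range(8):
            pair = augment(sample_patch_pair(hr, lr, 16, 2, trial), trial)
            re = degrade(pair.hr, 2)
            inner = (slice(None), slice(3, -3), slice(3, -3))
            assert np.allclose(re.data[inner], pair.lr.data[inner], atol=1e-5)


class TestImageIO:
    def test_8bit_gray_round_trip(self, tmp_path, rng):
        img = Image(np.round(rng.random((1, 9, 7)) * 255).astype(np.float32) / 255)
        write_image(img, tmp_path / "g.png")
        back = read_image(tmp_path / "g.png")
        assert back.bits == 8
        assert np.array_equal(back.data, img.data)

    @pytest.mark.parametrize("ext", ["png", "tif"])
    def test_16bit_round_trip(self, tmp_path, rng, ext):
        q = np.round(rng.random((1, 5, 6)) * 65535).astype(np.float32) / 65535
        img = Image(q, bits=16)
        write_image(img, tmp_path / f"g16.{ext}")
        back = read_image(tmp_path / f"g16.{ext}")
        assert back.bits == 16
        assert np.allclose(back.data, img.data, atol=1e-7)

    def test_rgb_channel_order_preserved(self, tmp_path):
        data = np.zeros((3, 4, 4), dtype=np.float32)
        data[0], data[1], data[2] = 10 / 255, 150 / 255, 240 / 255
        write_image(Image(data), tmp_path / "rgb.png")
        back = read_image(tmp_path / "rgb.png")
        assert back.channels == 3
        assert np.allclose(back.data[0], 10 / 255, atol=1e-7)
        assert np.allclose(back.data[2], 240 / 255, atol=1e-7)

    def test_unsupported_mode_names_the_file(self, tmp_path):
        from PIL import Image as PILImage
        p = tmp_path / "pal.png"
        PILImage.new("P", (4, 4)).save(p)
        with pytest.raises(ValueError, match="pal.png"):
            read_image(p)

    def test_unsupported_depth_rejected(self, tmp_path):
        img = Image(np.zeros((1, 4, 4), dtype=np.float32), bits=12)
        with pytest.raises(ValueError):
            write_image(img, tmp_path / "x.png")


class TestSplitsAndManifest:
    def test_ratio_20_2_1_on_23_items(self):
        labels = SplitSpec(seed=0).assign(23)
        assert labels.count("train") == 20
        assert labels.count("val") == 2
        assert labels.count("test") == 1

    def test_partition_is_exhaustive_and_reproducible(self):
        a = SplitSpec(seed=3).assign(10)
        b = SplitSpec(seed=3).assign(10)
        assert a == b
        assert len(a) == 10 and set(a) <= {"train", "val", "test"}

    def test_manifest_round_trip(self, tmp_path):
        rows = [("a.png", "train", 64, 64, 16), ("b.png", "test", 32, 48, 8)]
        write_manifest(rows, tmp_path / "m.csv")
        back = read_manifest(tmp_path / "m.csv")
        assert back[0]["split"] == "train" and back[1]["w"] == 48
        assert back[0]["path"] == tmp_path / "a.png"

    def test_bad_header_rejected(self, tmp_path):
        (tmp_path / "m.csv").write_text("x,y\n1,2\n")
        with pytest.raises(ValueError):
            read_manifest(tmp_path / "m.csv")


def test_image_validation():
    with pytest.raises(ValueError):
        Image(np.zeros((2, 4, 4)))          # 2 channels unsupported
    with pytest.raises(ValueError):
        Image(np.full((1, 4, 4), np.nan))
    img = Image(np.zeros((4, 4)))           # 2-D promoted to one channel
    assert img.channels == 1
    assert Image(np.zeros((1, 2, 2)), bits=16).value_range == 65535


def test_center_crop_to_multiple():
    img = Image(np.arange(5 * 7, dtype=np.float32).reshape(1, 5, 7) / 64)
    out = center_crop_to_multiple(img, 4)
    assert out.data.shape == (1, 4, 4)
    with pytest.raises(ValueError):
        center_crop_to_multiple(Image(np.zeros((1, 3, 3))), 4)
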