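"""Paired-stain I/O: loading, normalization, resizing, augmentation, splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image as PILImage

from he2ihc import stain_io as sio


def _write_png(path, arr):
    PILImage.fromarray(arr.astype(np.uint8)).save(path)


@pytest.fixture()
def pair_on_disk(tmp_path, rng):
    he = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
    ihc = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
    _write_png(tmp_path / "he.png", he)
    _write_png(tmp_path / "ihc.png", ihc)
    return tmp_path, he, ihc


class TestLoadPair:
    def test_shape_contract_and_roundtrip(self, pair_on_disk):
        tmp, he, ihc = pair_on_disk
        pair = sio.load_pair(tmp / "he.png", tmp / "ihc.png", sio.Her2Level(2))
        assert pair.he.data.shape == (32, 32, 3)
        assert pair.he.range == sio.RAW8
        np.testing.assert_array_equal(pair.he.data, he)   # lossless round trip
        np.testing.assert_array_equal(pair.ihc.data, ihc)
        assert pair.level.label == "2+"

    def test_mismatched_dimensions_raise_pairing_error(self, tmp_path, rng):
        _write_png(tmp_path / "a.png", rng.integers(0, 255, (32, 32, 3)))
        _write_png(tmp_path / "b.png", rng.integers(0, 255, (16, 16, 3)))
        with pytest.raises(ValueError, match="pairing error.*32.*16"):
            sio.load_pair(tmp_path / "a.png", tmp_path / "b.png", sio.Her2Level(0))

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nope.png"):
            sio.read_image(tmp_path / "nope.png")

    def test_grayscale_promoted_to_rgb(self, tmp_path, rng):
        gray = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        PILImage.fromarray(gray, mode="L").save(tmp_path / "g.png")
        img = sio.read_image(tmp_path / "g.png")
        assert img.data.shape == (16, 16, 3)


class TestNormalize:
    @pytest.mark.parametrize("value,expected", [(0, -1.0), (255, 1.0), (127.5, 0.0)])
    def test_endpoints_and_midpoint(self, value, expected):
        img = sio.Image(np.full((4, 4, 3), value, np.float32))
        out = sio.normalize(img)
        assert out.range == sio.NORM
        np.testing.assert_allclose(out.data, expected, atol=1e-7)

    def test_double_normalize_rejected(self):
        img = sio.normalize(sio.Image(np.zeros((4, 4, 3), np.float32)))
        with pytest.raises(ValueError, match="range tag"):
            sio.normalize(img)

    def test_denormalize_inverts_within_one_lsb(self, rng):
        raw = sio.Image(rng.integers(0, 256, (8, 8, 3)).astype(np.float32))
        back = sio.denormalize(sio.normalize(raw))
        assert np.abs(back.data - raw.data).max() < 1.0 / 255


class TestResize:
    def test_downscale_shape_and_tag(self, rng):
        img = sio.Image(rng.integers(0, 256, (128, 128, 3)).astype(np.float32))
        out = sio.resize_to(img, 32)
        assert out.data.shape == (32, 32, 3) and out.range == sio.RAW8

    def test_constancy_preserved(self):
        img = sio.Image(np.full((64, 64, 3), 37.0, np.float32))
        np.testing.assert_allclose(sio.resize_to(img, 16).data, 37.0, atol=1e-4)

    def test_identity_resize(self, rng):
        img = sio.Image(rng.integers(0, 256, (32, 32, 3)).astype(np.float32))
        np.testing.assert_array_equal(sio.resize_to(img, 32).data, img.data)

    def test_nonpositive_side_rejected(self):
        img = sio.Image(np.zeros((8, 8, 3), np.float32))
        with pytest.raises(ValueError):
            sio.resize_to(img, 0)


def _marker_pair(side=8):
    he = np.zeros((side, side, 3), np.float32)
    ihc = np.zeros((side, side, 3), np.float32)
    he[0, 0] = ihc[0, 0] = 255.0
    return sio.StainPair(sio.Image(he), sio.Image(ihc), sio.Her2Level(1), "m")


class TestAugment:
    def test_deterministic_under_seed(self, rng):
        pair = _marker_pair()
        a = sio.augment(pair, seed=7)
        b = sio.augment(pair, seed=7)
        np.testing.assert_array_equal(a.he.data, b.he.data)
        np.testing.assert_array_equal(a.ihc.data, b.ihc.data)

    @pytest.mark.parametrize("seed", range(24))
    def test_marker_lands_identically_in_both_images(self, seed):
        out = sio.augment(_marker_pair(), seed)
        he_pos = np.argwhere(out.he.data[:, :, 0] == 255.0)
        ihc_pos = np.argwhere(out.ihc.data[:, :, 0] == 255.0)
        np.testing.assert_array_equal(he_pos, ihc_pos)
        assert out.level.index == 1

    def test_pixel_multiset_preserved(self, rng):
        he = rng.integers(0, 256, (8, 8, 3)).astype(np.float32)
        ihc = rng.integers(0, 256, (8, 8, 3)).astype(np.float32)
        pair = sio.StainPair(sio.Image(he), sio.Image(ihc), sio.Her2Level(0), "p")
        out = sio.augment(pair, seed=5)
        assert sorted(out.he.data.ravel()) == sorted(he.ravel())
        assert sorted(out.ihc.data.ravel()) == sorted(ihc.ravel())


def _toy_manifest(n_per_level):
    pairs = [
        sio.PairRef(f"p{lvl}_{i}", f"he_{lvl}_{i}.png", f"ihc_{lvl}_{i}.png",
                    sio.Her2Level(lvl))
        for lvl in range(4) for i in range(n_per_level)
    ]
    return sio.Manifest(pairs)


class TestSplit:
    def test_exact_fractions_per_level(self):
        tr, va, te = sio.split_manifest(_toy_manifest(10), sio.SplitSpec((0.7, 0.2, 0.1), 0))
        for lvl in range(4):
            counts = [sum(p.level.index == lvl for p in m.pairs) for m in (tr, va, te)]
            assert counts == [7, 2, 1]

    def test_deterministic(self):
        spec = sio.SplitSpec((0.7, 0.2, 0.1), seed=42)
        a = sio.split_manifest(_toy_manifest(10), spec)
        b = sio.split_manifest(_toy_manifest(10), spec)
        for ma, mb in zip(a, b):
            assert [p.pair_id for p in ma.pairs] == [p.pair_id for p in mb.pairs]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           f=st.sampled_from([(0.7, 0.2, 0.1), (0.5, 0.25, 0.25), (1.0, 0.0, 0.0)]),
           n=st.integers(1, 17))
    def test_partition_is_disjoint_and_exhaustive(self, seed, f, n):
        m = _toy_manifest(n)
        parts = sio.split_manifest(m, sio.SplitSpec(f, seed))
        ids = [set(p.pair_id for p in part.pairs) for part in parts]
        assert ids[0] | ids[1] | ids[2] == {p.pair_id for p in m.pairs}
        assert sum(len(s) for s in ids) == len(m)  # pairwise disjoint

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            sio.split_manifest(sio.Manifest([]), sio.SplitSpec())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            sio.SplitSpec((0.5, 0.2, 0.1), 0)


def test_manifest_json_roundtrip(tmp_path):
    m = _toy_manifest(2)
    m.save(tmp_path / "m.json")
    back = sio.Manifest.load(tmp_path / "m.json")
    assert [p.pair_id for p in back.pairs] == [p.pair_id for p in m.pairs]
    assert [p.level.index for p in back.pairs] == [p.level.index for p in m.pairs]
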