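"""Image-quality metric suite against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest

from he2ihc import metrics as M
from he2ihc.nn import Tensor
from he2ihc.stain_io import write_image, Image


def _gray(rng, side=24):
    return rng.uniform(0, 255, size=(side, side)).astype(np.float64)


class TestSsim:
    def test_identity_is_one(self, rng):
        a = _gray(rng)
        assert M.ssim(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_black_vs_white_closed_form(self):
        a = np.zeros((16, 16))
        b = np.full((16, 16), 255.0)
        p = M.SsimParams()
        expected = p.c1 / (255.0 ** 2 + p.c1)  # c = s = 1 for constant images
        assert M.ssim(a, b, p) == pytest.approx(expected, rel=1e-6)

    def test_matches_per_window_brute_force(self, rng):
        a, b = _gray(rng, 16), _gray(rng, 16)
        p = M.SsimParams()
        w = M.gaussian_window(p.window, p.sigma)
        vals = []
        for i in range(16 - p.window + 1):
            for j in range(16 - p.window + 1):
                pa = a[i:i + p.window, j:j + p.window]
                pb = b[i:i + p.window, j:j + p.window]
                mx, my = (w * pa).sum(), (w * pb).sum()
                vx = (w * pa * pa).sum() - mx ** 2
                vy = (w * pb * pb).sum() - my ** 2
                cov = (w * pa * pb).sum() - mx * my
                l = (2 * mx * my + p.c1) / (mx ** 2 + my ** 2 + p.c1)
                c = (2 * math.sqrt(vx) * math.sqrt(vy) + p.c2) / (vx + vy + p.c2)
                s = (cov + p.c3) / (math.sqrt(vx) * math.sqrt(vy) + p.c3)
                vals.append(l * c * s)
        assert M.ssim(a, b, p) == pytest.approx(np.mean(vals), abs=1e-6)

    def test_symmetry_at_unit_exponents(self, rng):
        a, b = _gray(rng), _gray(rng)
        assert M.ssim(a, b) == pytest.approx(M.ssim(b, a), abs=1e-12)

    def test_agrees_with_skimage(self, rng):
        from skimage.metrics import structural_similarity
        a, b = _gray(rng, 32), _gray(rng, 32)
        ref = structural_similarity(a, b, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False, data_range=255)
        assert M.ssim(a, b) == pytest.approx(ref, abs=2e-3)


class TestPsnr:
    def test_identity_sentinel(self, rng):
        a = _gray(rng)
        p, mse = M.psnr(a, a)
        assert mse == 0.0 and p == math.inf

    def test_uniform_unit_difference(self):
        a = np.full((8, 8, 3), 100.0)
        p, mse = M.psnr(a, a + 1.0)
        assert mse == pytest.approx(1.0)
        assert p == pytest.approx(10 * math.log10(255 ** 2), abs=1e-6)

    def test_matches_brute_force(self, rng):
        a, b = _gray(rng), _gray(rng)
        p, mse = M.psnr(a, b)
        expect_mse = float(np.mean([(x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())]))
        assert mse == pytest.approx(expect_mse, rel=1e-6)
        assert p == pytest.approx(10 * math.log10(255 ** 2 / expect_mse), rel=1e-6)

    def test_strictly_decreasing_in_mse(self, rng):
        a = _gray(rng)
        p1, _ = M.psnr(a, a + 1.0)
        p2, _ = M.psnr(a, a + 2.0)
        assert p1 > p2


class TestVectorMetrics:
    def test_cosine_examples(self):
        assert M.cosine_similarity([1, 2, 2], [2, 4, 4]) == pytest.approx(1.0)
        assert M.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="zero"):
            M.cosine_similarity([0, 0], [0, 0])

    def test_euclidean_examples(self, rng):
        assert M.euclidean_distance([0, 0], [3, 4]) == pytest.approx(5.0)
        r, g = rng.normal(size=20), rng.normal(size=20)
        expect = math.sqrt(sum((a - b) ** 2 for a, b in zip(r, g)))
        assert M.euclidean_distance(r, g) == pytest.approx(expect, abs=1e-9)
        with pytest.raises(ValueError):
            M.euclidean_distance([1, 2], [1, 2, 3])


class TestFid:
    def test_identical_stats_give_zero(self, rng):
        f = rng.normal(size=(50, 4))
        s = M.gaussian_stats(f)
        assert M.fid(s, s) == pytest.approx(0.0, abs=1e-8)

    def test_one_dimensional_closed_form(self):
        a = M.GaussianStats(np.array([0.0]), np.array([[1.0]]), 10)
        b = M.GaussianStats(np.array([1.0]), np.array([[1.0]]), 10)
        assert M.fid(a, b) == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_covariances_match_elementwise_form(self, rng):
        d = 5
        mu1, mu2 = rng.normal(size=d), rng.normal(size=d)
        v1, v2 = rng.uniform(0.5, 2.0, d), rng.uniform(0.5, 2.0, d)
        a = M.GaussianStats(mu1, np.diag(v1), 10)
        b = M.GaussianStats(mu2, np.diag(v2), 10)
        expect = np.sum((mu1 - mu2) ** 2) + np.sum((np.sqrt(v1) - np.sqrt(v2)) ** 2)
        assert M.fid(a, b) == pytest.approx(expect, abs=1e-8)

    def test_symmetry(self, rng):
        a = M.gaussian_stats(rng.normal(size=(40, 3)))
        b = M.gaussian_stats(rng.normal(1.0, 2.0, size=(40, 3)))
        assert M.fid(a, b) == pytest.approx(M.fid(b, a), rel=1e-8)

    def test_non_psd_rejected(self):
        bad = M.GaussianStats(np.zeros(2), np.array([[1.0, 0.0], [0.0, -1.0]]), 5)
        ok = M.GaussianStats(np.zeros(2), np.eye(2), 5)
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            M.fid(bad, ok)


class TestLpips:
    def test_identity_is_zero(self, rng):
        a = rng.uniform(0, 255, (8, 8, 3))
        ext = lambda t: [t]
        assert M.lpips(a, a, ext, [np.ones(3)]) == pytest.approx(0.0, abs=1e-12)

    def test_toy_two_layer_extractor_matches_hand_formula(self, rng):
        a = rng.uniform(0, 255, (6, 6, 3))
        b = rng.uniform(0, 255, (6, 6, 3))
        ext = lambda t: [t, t * 2.0]
        weights = [np.array([0.5, 1.0, 2.0]), np.array([1.0, 1.0, 1.0])]
        got = M.lpips(a, b, ext, weights)

        def unit(x):
            return x / np.sqrt((x ** 2).sum(axis=1, keepdims=True) + 1e-10)

        na = (a / 127.5 - 1).transpose(2, 0, 1)[None]
        nb = (b / 127.5 - 1).transpose(2, 0, 1)[None]
        expect = 0.0
        for layer_a, layer_b, w in zip([na, na * 2], [nb, nb * 2], weights):
            d2 = (unit(layer_a) - unit(layer_b)) ** 2
            expect += (d2 * w.reshape(1, -1, 1, 1)).sum(axis=1).mean()
        assert got == pytest.approx(expect, abs=1e-6)

    def test_missing_weights_rejected(self, rng):
        a = rng.uniform(0, 255, (6, 6, 3))
        with pytest.raises(ValueError, match="weight"):
            M.lpips(a, a, lambda t: [t, t], [np.ones(3)])


def _write_set(root, arrays):
    root.mkdir(parents=True, exist_ok=True)
    for i, arr in enumerate(arrays):
        write_image(Image(arr.astype(np.float32)), root / f"img{i:02d}.png")


class TestReport:
    def test_self_comparison_yields_identity_row(self, tmp_path, rng):
        arrays = [rng.integers(0, 256, (32, 32, 3)) for _ in range(4)]
        _write_set(tmp_path / "real", arrays)
        rep = M.report(tmp_path / "real", tmp_path / "real")
        assert rep.mse == 0.0 and rep.psnr == math.inf
        assert rep.ssim == pytest.approx(1.0, abs=1e-9)
        assert rep.fid == pytest.approx(0.0, abs=1e-6)
        assert rep.lpips == pytest.approx(0.0, abs=1e-9)
        assert rep.cs == pytest.approx(1.0, abs=1e-9)
        assert rep.ed == 0.0
        assert rep.dl_features == pytest.approx(1.0, abs=1e-6)

    def test_uniform_offset_mse_is_offset_squared(self, tmp_path, rng):
        real = [rng.integers(40, 200, (24, 24, 3)) for _ in range(10)]
        fake = [arr + 7 for arr in real]
        _write_set(tmp_path / "real", real)
        _write_set(tmp_path / "fake", fake)
        rep = M.report(tmp_path / "real", tmp_path / "fake")
        assert rep.mse == pytest.approx(49.0, abs=1e-9)

    def test_unmatched_filenames_listed(self, tmp_path, rng):
        _write_set(tmp_path / "real", [rng.integers(0, 255, (16, 16, 3))])
        (tmp_path / "fake").mkdir()
        write_image(Image(rng.integers(0, 255, (16, 16, 3)).astype(np.float32)),
                    tmp_path / "fake" / "other.png")
        with pytest.raises(ValueError, match="unmatched"):
            M.report(tmp_path / "real", tmp_path / "fake")


class TestPixelDistribution:
    def test_identical_directories_have_zero_divergence(self, tmp_path, rng):
        arrays = [rng.integers(0, 256, (16, 16, 3)) for _ in range(3)]
        _write_set(tmp_path / "real", arrays)
        hr, hf, div = M.pixel_distribution(tmp_path / "real", tmp_path / "real")
        assert div == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(hr.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_shift_shifts_histogram(self, tmp_path, rng):
        real = [rng.integers(10, 100, (16, 16, 3)) for _ in range(3)]
        fake = [arr + 20 for arr in real]
        _write_set(tmp_path / "real", real)
        _write_set(tmp_path / "fake", fake)
        hr, hf, div = M.pixel_distribution(tmp_path / "real", tmp_path / "fake")
        np.testing.assert_allclose(hf[:, 30:120], hr[:, 10:100], atol=1e-12)
        assert div > 0.0

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "real").mkdir()
        (tmp_path / "fake").mkdir()
        with pytest.raises(ValueError, match="no images"):
            M.pixel_distribution(tmp_path / "real", tmp_path / "fake")
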