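"""GAN objectives against closed forms and element-wise brute force."""

import numpy as np
import pytest

from he2ihc.nn import Tensor
from he2ihc.discriminator import DiscriminatorTaps, ScaleTaps
from he2ihc.losses import (
    LossWeights, adversarial_loss, feature_matching_loss, l1_loss,
    perceptual_loss, total_loss,
)


def _taps_from_logits(logit_arrays):
    scales = []
    for arr in logit_arrays:
        t = Tensor(np.asarray(arr, np.float32))
        scales.append(ScaleTaps([t], t))
    return DiscriminatorTaps(scales)


def _random_taps(rng, n_scales=3, n_layers=4, requires_grad=False):
    scales = []
    for s in range(n_scales):
        feats = [Tensor(rng.normal(size=(2, 3, 5 - s, 5 - s)).astype(np.float32),
                        requires_grad=requires_grad)
                 for _ in range(n_layers)]
        scales.append(ScaleTaps(feats, feats[-1]))
    return DiscriminatorTaps(scales)


class TestAdversarial:
    def test_optimal_discriminator_attains_objective_zero(self):
        # D(x,y) -> 1 and D(x,G(x)) -> 0: both log terms vanish
        big = 80.0
        real = _taps_from_logits([np.full((1, 1, 4, 4), big)] * 3)
        fake = _taps_from_logits([np.full((1, 1, 4, 4), -big)] * 3)
        gan_d, _ = adversarial_loss(real, fake)
        assert abs(-gan_d.item()) < 1e-6

    def test_undecided_discriminator_value_is_two_log_half(self):
        zeros = [np.zeros((1, 1, 4, 4))] * 3
        gan_d, gan_g = adversarial_loss(_taps_from_logits(zeros), _taps_from_logits(zeros))
        assert -gan_d.item() == pytest.approx(2 * np.log(0.5), abs=1e-6)
        assert gan_g.item() == pytest.approx(-np.log(0.5), abs=1e-6)

    def test_matches_per_element_formula_on_random_logits(self, rng):
        real_logits = [rng.normal(size=(2, 1, 3, 3)) for _ in range(3)]
        fake_logits = [rng.normal(size=(2, 1, 3, 3)) for _ in range(3)]
        gan_d, gan_g = adversarial_loss(_taps_from_logits(real_logits),
                                        _taps_from_logits(fake_logits))

        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))

        expect_val = np.mean([
            np.log(sig(r)).mean() + np.log(1 - sig(f)).mean()
            for r, f in zip(real_logits, fake_logits)
        ])
        expect_g = np.mean([-np.log(sig(f)).mean() for f in fake_logits])
        assert -gan_d.item() == pytest.approx(expect_val, abs=1e-6)
        assert gan_g.item() == pytest.approx(expect_g, abs=1e-6)

    def test_lsgan_variant(self):
        zeros = [np.zeros((1, 1, 2, 2))] * 3
        gan_d, gan_g = adversarial_loss(_taps_from_logits(zeros),
                                        _taps_from_logits(zeros), mode="lsgan")
        assert gan_d.item() == pytest.approx(0.5, abs=1e-6)
        assert gan_g.item() == pytest.approx(1.0, abs=1e-6)

    def test_scale_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="scale count"):
            adversarial_loss(_random_taps(rng, n_scales=3), _random_taps(rng, n_scales=2))


class TestFeatureMatching:
    def test_identical_features_give_zero(self, rng):
        taps = _random_taps(rng)
        assert feature_matching_loss(taps, taps, taps, taps).item() == 0.0

    def test_unit_offset_gives_two(self, rng):
        real = _random_taps(rng)
        fake = DiscriminatorTaps([
            ScaleTaps([Tensor(f.data + 1.0) for f in s.features], None)
            for s in real.scales
        ])
        # full-scale expectation contributes 1, the low-resolution pair another 1
        assert feature_matching_loss(real, fake, real, fake).item() == pytest.approx(2.0, abs=1e-6)

    def test_matches_brute_force(self, rng):
        real, fake = _random_taps(rng), _random_taps(rng)
        got = feature_matching_loss(real, fake).item()
        per_scale = []
        for sr, sf in zip(real.scales, fake.scales):
            vals = [np.abs(fr.data - ff.data).mean()
                    for fr, ff in zip(sr.features, sf.features)]
            per_scale.append(np.mean(vals))
        assert got == pytest.approx(np.mean(per_scale), abs=1e-6)

    def test_common_shift_invariance(self, rng):
        real, fake = _random_taps(rng), _random_taps(rng)
        shifted = lambda taps: DiscriminatorTaps([
            ScaleTaps([Tensor(f.data + 0.37) for f in s.features], None)
            for s in taps.scales
        ])
        a = feature_matching_loss(real, fake).item()
        b = feature_matching_loss(shifted(real), shifted(fake)).item()
        assert a == pytest.approx(b, abs=1e-5)


class TestPerceptual:
    def test_identity_extractor_equals_mean_absolute_difference(self, rng):
        y = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        f = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        got = perceptual_loss(y, f, lambda t: [t]).item()
        assert got == pytest.approx(np.abs(y.data - f.data).mean(), abs=1e-6)

    def test_equal_inputs_give_zero(self, rng):
        y = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        assert perceptual_loss(y, y, lambda t: [t, t * 2.0]).item() == 0.0

    def test_two_layer_toy_extractor_matches_brute_force(self, rng):
        y = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        f = Tensor(rng.normal(size=(1, 3, 6, 6)).astype(np.float32))
        extractor = lambda t: [t * 1.5, t.mean(axis=(2, 3), keepdims=True)]
        got = perceptual_loss(y, f, extractor).item()
        expect = (np.abs(1.5 * y.data - 1.5 * f.data).mean()
                  + np.abs(y.data.mean((2, 3)) - f.data.mean((2, 3))).mean())
        assert got == pytest.approx(expect, abs=1e-6)


class TestL1AndTotal:
    def test_l1_constant_difference(self, rng):
        y = Tensor(rng.normal(size=(2, 3, 4, 4)).astype(np.float32))
        assert l1_loss(y, Tensor(y.data + 0.75)).item() == pytest.approx(0.75, abs=1e-6)
        assert l1_loss(y, y).item() == 0.0
        with pytest.raises(ValueError):
            l1_loss(y, Tensor(np.zeros((1, 3, 4, 4), np.float32)))

    def test_total_is_weighted_sum_with_breakdown_invariant(self, rng):
        parts = [Tensor(np.float32(v)) for v in (1.0, 2.0, 3.0, 4.0)]
        w = LossWeights(1.0, 1.0, 1.0, 1.0)
        total, br = total_loss(*parts, w)
        assert total.item() == pytest.approx(10.0, abs=1e-6)
        w = LossWeights()  # defaults
        vals = [float(v) for v in rng.uniform(0, 2, size=4)]
        total, br = total_loss(*[Tensor(np.float32(v)) for v in vals], w)
        expected = (w.lambda_gan * vals[0] + w.lambda_fm * vals[1]
                    + w.lambda_vgg * vals[2] + w.lambda_l1 * vals[3])
        assert total.item() == pytest.approx(expected, rel=1e-6)
        recomputed = (w.lambda_gan * br.gan_g + w.lambda_vgg * br.vgg
                      + w.lambda_fm * br.fm + w.lambda_l1 * br.l1)
        assert br.total_g == pytest.approx(recomputed, abs=1e-6)

    def test_zero_weights_give_zero_total(self):
        parts = [Tensor(np.float32(v)) for v in (9.0, 9.0, 9.0, 9.0)]
        total, _ = total_loss(*parts, LossWeights(0, 0, 0, 0))
        assert total.item() == 0.0

    def test_nan_part_raises_divergence_error(self):
        parts = [Tensor(np.float32(np.nan))] + [Tensor(np.float32(1.0))] * 3
        with pytest.raises(FloatingPointError, match="divergence"):
            total_loss(*parts, LossWeights())

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_l1=-1.0)
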