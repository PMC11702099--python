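"""GAN training objectives: adversarial, feature-matching, perceptual, L1
and their weighted combination.

The adversarial objective is the log (vanilla) GAN form

    L_GAN = E[log D(x,y)] + E[log(1 - D(x,G(x)))]

maximized by D (so the discriminator minimizes its negation) with the
non-saturating generator term -E[log D(x,G(x))]; a least-squares variant is
available behind ``mode="lsgan"``.  The feature-matching loss compares
discriminator taps of real and generated pairs, element-count-normalized
per layer, averaged over layers and scales, for both the full-resolution
and the low-resolution generator outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn import Tensor
from .discriminator import DiscriminatorTaps


@dataclass(frozen=True)
class LossWeights:
    lambda_gan: float = 1.0
    lambda_vgg: float = 10.0
    lambda_fm: float = 10.0
    lambda_l1: float = 100.0

    def __post_init__(self):
        if min(self.lambda_gan, self.lambda_vgg, self.lambda_fm, self.lambda_l1) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    gan_g: float
    gan_d: float
    fm: float
    vgg: float
    l1: float
    total_g: float

    def as_dict(self) -> dict:
        return dict(gan_g=self.gan_g, gan_d=self.gan_d, fm=self.fm,
                    vgg=self.vgg, l1=self.l1, total_g=self.total_g)


def _check_scales(a: DiscriminatorTaps, b: DiscriminatorTaps) -> None:
    if len(a.scales) != len(b.scales):
        raise ValueError(f"scale count mismatch: {len(a.scales)} vs {len(b.scales)}")


def adversarial_loss(real_taps: DiscriminatorTaps, fake_taps: DiscriminatorTaps,
                     mode: str = "vanilla") -> tuple[Tensor, Tensor]:
    """Returns (gan_d, gan_g), both to be *minimized*.

    For the vanilla mode, ``-gan_d`` is the raw value of the log-GAN
    objective, averaged over scales and patch positions.
    """
    _check_scales(real_taps, fake_taps)
    n = len(real_taps.scales)
    d_terms, g_terms = [], []
    for sr, sf in zip(real_taps.scales, fake_taps.scales):
        lr, lf = sr.patch_logits, sf.patch_logits
        if mode == "vanilla":
            # log D = logsigmoid(l); log(1-D) = logsigmoid(-l)
            d_terms.append(lr.logsigmoid().mean() + (-lf).logsigmoid().mean())
            g_terms.append(-(lf.logsigmoid().mean()))
        elif mode == "lsgan":
            d_terms.append(-0.5 * ((lr - 1.0).pow(2).mean() + lf.pow(2).mean()))
            g_terms.append((lf - 1.0).pow(2).mean())
        else:
            raise ValueError(f"unknown adversarial mode {mode!r}")
    gan_d = -(sum(d_terms[1:], d_terms[0]) * (1.0 / n))
    gan_g = sum(g_terms[1:], g_terms[0]) * (1.0 / n)
    return gan_d, gan_g


def _fm_term(real_taps: DiscriminatorTaps, fake_taps: DiscriminatorTaps) -> Tensor:
    _check_scales(real_taps, fake_taps)
    scale_means = []
    for sr, sf in zip(real_taps.scales, fake_taps.scales):
        if len(sr.features) != len(sf.features):
            raise ValueError("feature layer count mismatch between real and fake taps")
        layer_terms = [
            (fr.detach() - ff).abs().mean()   # (1/N_i)·||Δ||₁ per sample
            for fr, ff in zip(sr.features, sf.features)
        ]
        scale_means.append(sum(layer_terms[1:], layer_terms[0]) * (1.0 / len(layer_terms)))
    return sum(scale_means[1:], scale_means[0]) * (1.0 / len(scale_means))


def feature_matching_loss(real_taps, fake_taps, real_low_taps=None,
                          fake_low_taps=None) -> Tensor:
    """Both expectations of the feature-matching objective: the full-scale
    pair plus (when provided) the low-resolution pair."""
    loss = _fm_term(real_taps, fake_taps)
    if real_low_taps is not None and fake_low_taps is not None:
        loss = loss + _fm_term(real_low_taps, fake_low_taps)
    return loss


def perceptual_loss(y: Tensor, fake: Tensor, extractor) -> Tensor:
    """Sum over extractor layers of element-normalized L1 feature distance."""
    feats_real = extractor(y.detach())
    feats_fake = extractor(fake)
    if len(feats_real) != len(feats_fake):
        raise ValueError("perceptual extractor returned mismatched layer counts")
    terms = [(fr.detach() - ff).abs().mean() for fr, ff in zip(feats_real, feats_fake)]
    return sum(terms[1:], terms[0])


def l1_loss(y: Tensor, fake: Tensor) -> Tensor:
    if y.shape != fake.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {fake.shape}")
    return (y - fake).abs().mean()


def total_loss(gan_g: Tensor, fm: Tensor, vgg: Tensor, l1: Tensor,
               w: LossWeights, gan_d: Tensor | None = None):
    """Weighted sum; returns (total tensor for backprop, float breakdown)."""
    total = (w.lambda_gan * gan_g + w.lambda_vgg * vgg
             + w.lambda_fm * fm + w.lambda_l1 * l1)
    parts = [gan_g.item(), fm.item(), vgg.item(), l1.item(), total.item()]
    if any(p != p for p in parts):  # NaN check
        raise FloatingPointError(f"training divergence: non-finite loss parts {parts}")
    breakdown = LossBreakdown(
        gan_g=parts[0], gan_d=gan_d.item() if gan_d is not None else float("nan"),
        fm=parts[1], vgg=parts[2], l1=parts[3], total_g=parts[4],
    )
    return total, breakdown
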