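"""Three-scale conditional PatchGAN discriminator ensemble.

Each scale sees the channel-concatenated (H&E, IHC-or-fake) pair — at the
original, 1/2 and 1/4 resolution, downsampled by 3×3 stride-2 average
pooling — and applies 4×4 stride-2 convolutions with widths doubling from a
base of 64, instance norm (no affine) and leaky ReLU after every layer
except the first, then a final 1-channel patch-logit convolution.  The four
body activations plus the logit map form the L = 5 feature taps of the
feature-matching loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat
from .nn import functional as F


@dataclass(frozen=True)
class DiscriminatorConfig:
    base_width: int = 64
    n_body_layers: int = 4
    n_scales: int = 3

    @property
    def widths(self) -> tuple:
        return tuple(self.base_width * 2 ** i for i in range(self.n_body_layers))


@dataclass
class ScaleTaps:
    features: list          # L feature maps (body activations + logits)
    patch_logits: Tensor    # alias of features[-1]

    @property
    def element_counts(self) -> list:
        return [int(np.prod(f.shape[1:])) for f in self.features]


@dataclass
class DiscriminatorTaps:
    scales: list  # n_scales ScaleTaps

    @property
    def layer_count(self) -> int:
        return len(self.scales[0].features)


class PatchDiscriminator(nn.Module):
    """Single-scale 70×70-receptive-field-style PatchGAN on a 6-channel pair."""

    def __init__(self, cfg: DiscriminatorConfig, *, rng):
        widths = cfg.widths
        self.convs = []
        cin = 6
        for w in widths:
            self.convs.append(nn.Conv2d(cin, w, 4, stride=2, pad=1, rng=rng))
            cin = w
        self.norms = [None] + [nn.InstanceNorm2d(w, affine=False) for w in widths[1:]]
        self.logit_conv = nn.Conv2d(cin, 1, 4, stride=1, pad=1, rng=rng)

    def forward(self, xy: Tensor) -> ScaleTaps:
        feats = []
        h = xy
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = h.leaky_relu(0.2)
            feats.append(h)
        logits = self.logit_conv(h)
        feats.append(logits)
        return ScaleTaps(feats, logits)


class MultiScaleDiscriminator(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.scales = [PatchDiscriminator(cfg, rng=rng) for _ in range(cfg.n_scales)]

    def discriminate(self, x: Tensor, y_or_fake: Tensor) -> DiscriminatorTaps:
        if x.shape != y_or_fake.shape:
            raise ValueError(f"shape mismatch: {x.shape} vs {y_or_fake.shape}")
        xy = concat([x, y_or_fake], axis=1)
        taps = []
        for d in self.scales:
            taps.append(d(xy))
            xy = F.avg_pool2d(xy, 3, 2, 1)
        return DiscriminatorTaps(taps)

    forward = discriminate
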