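"""Deep feature extractors for the perceptual loss, LPIPS and FID.

The package's default extractor is a *fixed, seeded, random-weight*
convolutional pyramid: weights are drawn once from a seeded generator and
never trained.  Random convolutional features are a recognized basis for
perceptual distances and two-sample statistics; they make every
feature-space metric fully reproducible offline.  The loss and metric
formulas are extractor-agnostic, so a learned backbone can be plugged in
through the same callable interface.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F


class RandomFeaturePyramid(nn.Module):
    """Stride-2 conv pyramid returning per-stage feature maps.

    forward(x) -> list of L feature tensors; ``pooled(x)`` -> (N, feat_dim)
    spatially pooled features of the deepest stage, for FID-style statistics.
    """

    def __init__(self, widths=(16, 32, 64, 128), seed: int = 7):
        rng = np.random.default_rng(seed)
        self.convs = []
        cin = 3
        for w in widths:
            self.convs.append(nn.Conv2d(cin, w, 3, stride=2, rng=rng))
            cin = w
        for p in self.parameters():   # frozen: never trained
            p.requires_grad = False
        # re-mark tensors so graph building still flows gradients through x
        self.widths = tuple(widths)

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(0.2)
            feats.append(h)
        return feats

    def pooled(self, x: Tensor) -> np.ndarray:
        return self.forward(x)[-1].data.mean(axis=(2, 3))


class LpipsWeights:
    """Per-layer, per-channel non-negative linear weights (seeded)."""

    def __init__(self, widths=(16, 32, 64, 128), seed: int = 11):
        rng = np.random.default_rng(seed)
        self.per_layer = [rng.uniform(0.0, 1.0, size=w).astype(np.float32) for w in widths]


def default_extractor(seed: int = 7) -> RandomFeaturePyramid:
    return RandomFeaturePyramid(seed=seed)


def default_lpips_weights(extractor: RandomFeaturePyramid, seed: int = 11) -> LpipsWeights:
    return LpipsWeights(widths=extractor.widths, seed=seed)
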