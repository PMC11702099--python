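"""Dual-scale coupled generator.

Two encoders — a full-resolution path (7×7 stem + three stride-2 downsamples
to a 1/8-scale feature map) and a low-resolution path operating on the 4×
downsampled input (stem and first downsample *shared* with the full path,
then one more downsample to 1/16 scale) — feed inverted-residual transformer
stacks (three blocks on the full path, one on the low path).  Classifier
feature taps and the low path's transformer output are fused into the full
path before its transformer.  Each decoder upsamples with stride-2 transposed
convolutions whose normalization is AdaIN conditioned on the HER2 level, and
emits a tanh-bounded RGB image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat
from .nn import functional as F
from .stain_io import Her2Level


@dataclass(frozen=True)
class GeneratorConfig:
    base_width: int = 64           # stem output channels; doubled per downsample
    ir_expansion: int = 4
    label_embed_dim: int = 64
    adain_hidden: int = 128
    tap_channels: tuple = (24, 40)  # classifier feature widths at strides 8, 16
    full_downsamples: int = 3       # fixed by the architecture
    low_downsamples: int = 2
    full_ir_blocks: int = 3
    low_ir_blocks: int = 1

    def __post_init__(self):
        if (self.full_downsamples, self.low_downsamples) != (3, 2):
            raise ValueError("architecture requires 3 full / 2 low downsamples")
        if (self.full_ir_blocks, self.low_ir_blocks) != (3, 1):
            raise ValueError("architecture requires 3 full / 1 low transformer blocks")
        if self.base_width <= 0:
            raise ValueError("base_width must be positive")


@dataclass
class GeneratorOutput:
    full: Tensor        # G(x), (N,3,S,S) in [-1,1]
    low_input: Tensor   # x_s,  (N,3,S/4,S/4)
    low_fake: Tensor    # G(x_s)
    level: list         # conditioning levels


class ConvINLReLU(nn.Module):
    def __init__(self, cin, cout, k, stride, *, rng):
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, rng=rng)
        self.norm = nn.InstanceNorm2d(cout)

    def forward(self, x):
        return self.norm(self.conv(x)).leaky_relu(0.2)


class InvertedResidual(nn.Module):
    """1×1 expansion → 3×3 depthwise → 1×1 projection, with residual add
    (stride 1, equal in/out width)."""

    def __init__(self, c, expansion, *, rng):
        ce = c * expansion
        self.expand = nn.Conv2d(c, ce, 1, rng=rng)
        self.n1 = nn.InstanceNorm2d(ce)
        self.dw = nn.DepthwiseConv2d(ce, 3, rng=rng)
        self.n2 = nn.InstanceNorm2d(ce)
        self.project = nn.Conv2d(ce, c, 1, rng=rng)
        self.n3 = nn.InstanceNorm2d(c)

    def forward(self, x):
        h = self.n1(self.expand(x)).leaky_relu(0.2)
        h = self.n2(self.dw(h)).leaky_relu(0.2)
        return x + self.n3(self.project(h))


class AdaIN(nn.Module):
    """Level embedding → 2-layer MLP → per-channel (gamma, beta); the feature
    map is spatially standardized then scaled/shifted."""

    def __init__(self, c, embed_dim, hidden, *, rng):
        self.c = c
        self.fc1 = nn.Linear(embed_dim, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, 2 * c, rng=rng)

    def params_for(self, emb: Tensor):
        h = self.fc2(self.fc1(emb).relu())
        # identity-initialized style: gamma = 1 + dgamma
        g = Tensor(np.ones(1, np.float32)) + _take(h, 0, self.c)
        b = _take(h, self.c, 2 * self.c)
        return g, b

    def forward(self, x, emb):
        if x.shape[1] != self.c:
            raise ValueError(f"AdaIN channel mismatch: map has {x.shape[1]}, params for {self.c}")
        g, b = self.params_for(emb)
        return F.adain(x, g, b)


def _take(t: Tensor, a: int, b: int) -> Tensor:
    """Column slice of a 2-D tensor, differentiable."""
    out = Tensor(t.data[:, a:b], _children=(t,))

    def bw(g):
        full = np.zeros_like(t.data)
        full[:, a:b] = g
        t._acc(full)

    out._backward = bw
    return out


class UpBlock(nn.Module):
    def __init__(self, cin, cout, embed_dim, hidden, *, rng):
        self.up = nn.ConvTranspose2d(cin, cout, 3, stride=2, rng=rng)
        self.adain = AdaIN(cout, embed_dim, hidden, rng=rng)

    def forward(self, x, emb):
        return self.adain(self.up(x), emb).relu()


class DualScaleGenerator(nn.Module):
    def __init__(self, cfg: GeneratorConfig = GeneratorConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        w = cfg.base_width
        e = cfg.ir_expansion
        ed, ah = cfg.label_embed_dim, cfg.adain_hidden

        # shared stem + first downsample (single storage for both encoders)
        self.stem = ConvINLReLU(3, w, 7, 1, rng=rng)
        self.down1 = ConvINLReLU(w, 2 * w, 3, 2, rng=rng)
        # full-path remainder
        self.down2 = ConvINLReLU(2 * w, 4 * w, 3, 2, rng=rng)
        self.down3 = ConvINLReLU(4 * w, 8 * w, 3, 2, rng=rng)
        # low-path remainder
        self.low_down2 = ConvINLReLU(2 * w, 4 * w, 3, 2, rng=rng)

        t32, t16 = cfg.tap_channels
        fuse_in = 8 * w + 4 * w + t32 + t16
        self.fuse_conv = nn.Conv2d(fuse_in, 8 * w, 1, rng=rng)
        self.fuse_norm = nn.InstanceNorm2d(8 * w)

        self.embed = nn.Embedding(4, ed, rng=rng)
        self.full_ir = [InvertedResidual(8 * w, e, rng=rng) for _ in range(cfg.full_ir_blocks)]
        self.low_ir = [InvertedResidual(4 * w, e, rng=rng) for _ in range(cfg.low_ir_blocks)]

        self.full_up = [
            UpBlock(8 * w, 4 * w, ed, ah, rng=rng),
            UpBlock(4 * w, 2 * w, ed, ah, rng=rng),
            UpBlock(2 * w, w, ed, ah, rng=rng),
        ]
        self.full_out = nn.Conv2d(w, 3, 7, rng=rng)
        # the low decoder needs two stride-2 stages to return from 1/16 to
        # 1/4 scale (64x64 for a 256 input)
        self.low_up = [
            UpBlock(4 * w, 2 * w, ed, ah, rng=rng),
            UpBlock(2 * w, w, ed, ah, rng=rng),
        ]
        self.low_out = nn.Conv2d(w, 3, 7, rng=rng)

    # ------------------------------------------------------------- encoders
    def encode_full(self, x: Tensor) -> Tensor:
        """256→32 path: 7×7 stem then three stride-2 convs (IN + leaky ReLU)."""
        return self.down3(self.down2(self.down1(self.stem(x))))

    def encode_low(self, x_s: Tensor) -> Tensor:
        """64→16 path reusing the shared stem and first downsample."""
        return self.low_down2(self.down1(self.stem(x_s)))

    # ---------------------------------------------------------------- fusion
    def fuse_features(self, f_full: Tensor, f_low: Tensor, taps: dict | None) -> Tensor:
        """Concatenate the 1/8-scale full-path map, the (upsampled) low-path
        map and the (upsampled, gradient-detached) classifier taps, then
        project back to the transformer width with a 1×1 conv."""
        side = f_full.shape[2]
        n = f_full.shape[0]
        t32, t16 = self.cfg.tap_channels
        if taps is None:
            tap8 = Tensor(np.zeros((n, t32, side, side), np.float32))
            tap16 = Tensor(np.zeros((n, t16, side, side), np.float32))
        else:
            if "s8" not in taps or "s16" not in taps:
                raise KeyError("classifier taps must provide 's8' and 's16' feature maps")
            tap8 = F.bilinear_resize(taps["s8"].detach(), side)
            tap16 = F.bilinear_resize(taps["s16"].detach(), side)
        f_low_up = F.bilinear_resize(f_low, side)
        h = concat([f_full, f_low_up, tap8, tap16], axis=1)
        return self.fuse_norm(self.fuse_conv(h)).leaky_relu(0.2)

    # -------------------------------------------------------------- generate
    def generate(self, x: Tensor, levels: list[Her2Level] | Her2Level,
                 taps: dict | None) -> GeneratorOutput:
        if isinstance(levels, Her2Level):
            levels = [levels] * x.shape[0]
        if len(levels) != x.shape[0]:
            raise ValueError("one HER2 level per batch element required")
        side = x.shape[2]
        if side % 16:
            raise ValueError(f"input side must be divisible by 16, got {side}")
        idx = np.array([l.index for l in levels])
        emb = F.embedding(idx, self.embed.w)

        x_s = F.bilinear_resize(x, side // 4)
        f_low = self.encode_low(x_s)
        for block in self.low_ir:
            f_low = block(f_low)

        f_full = self.encode_full(x)
        h = self.fuse_features(f_full, f_low, taps)
        for block in self.full_ir:
            h = block(h)
        for up in self.full_up:
            h = up(h, emb)
        full = self.full_out(h).tanh()

        hl = f_low
        for up in self.low_up:
            hl = up(hl, emb)
        low_fake = self.low_out(hl).tanh()
        return GeneratorOutput(full, x_s, low_fake, list(levels))
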