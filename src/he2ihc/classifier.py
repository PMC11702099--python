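"""HER2-level backbone classifier.

A MobileNetV3-style stack — stem conv, inverted-residual bottlenecks with
squeeze-excitation and hard-swish, a 1×1 head conv, global pooling and two
fully-connected layers — trained with cross-entropy to score H&E patches
into the four HER2 levels.  Besides class probabilities it exposes two
intermediate feature maps (at strides 8 and 16) that the generator fuses
with its encoder outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .stain_io import Her2Level, Image, Manifest, load_manifest_pair, normalize, resize_to


@dataclass(frozen=True)
class BlockSpec:
    """One inverted-residual bottleneck: kernel 3, given expansion width,
    output width, stride, optional squeeze-excitation, activation."""

    exp: int
    out: int
    stride: int
    se: bool
    act: str  # "relu" | "hswish"


@dataclass(frozen=True)
class ClassifierConfig:
    stem: int = 16
    blocks: tuple = (
        BlockSpec(16, 16, 2, True, "relu"),     # -> stride 4
        BlockSpec(72, 24, 2, False, "relu"),    # -> stride 8
        BlockSpec(88, 24, 1, False, "relu"),    # tap @ stride 8
        BlockSpec(96, 40, 2, True, "hswish"),   # -> stride 16
        BlockSpec(240, 40, 1, True, "hswish"),  # tap @ stride 16
        BlockSpec(120, 48, 2, True, "hswish"),  # -> stride 32
    )
    tap8_index: int = 2
    tap16_index: int = 4
    head_conv: int = 288
    head_hidden: int = 512
    n_classes: int = 4

    @property
    def tap_channels(self) -> tuple:
        return (self.blocks[self.tap8_index].out, self.blocks[self.tap16_index].out)


def scaled_classifier_config(width_scale: float = 1.0, head_hidden: int | None = None) -> ClassifierConfig:
    """Scale every channel width by ``width_scale`` (min 4)."""
    s = lambda c: max(4, int(round(c * width_scale)))
    base = ClassifierConfig()
    blocks = tuple(
        BlockSpec(s(b.exp), s(b.out), b.stride, b.se, b.act) for b in base.blocks
    )
    return ClassifierConfig(
        stem=s(base.stem), blocks=blocks,
        head_conv=s(base.head_conv),
        head_hidden=head_hidden if head_hidden is not None else s(base.head_hidden),
    )


@dataclass
class ClassifierOutput:
    probs: np.ndarray                  # (N, 4), rows sum to 1
    predicted: list                    # list[Her2Level]
    taps: dict                         # {"s8": Tensor, "s16": Tensor}
    penultimate: np.ndarray | None = None  # (N, head_hidden) deep features


class SqueezeExcite(nn.Module):
    def __init__(self, c, *, rng):
        hidden = max(4, c // 4)
        self.fc1 = nn.Linear(c, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, c, rng=rng)

    def forward(self, x):
        s = F.global_avg_pool(x)
        s = self.fc2(self.fc1(s).relu()).hardsigmoid()
        n, c = s.shape
        return x * s.reshape(n, c, 1, 1)


def _act(x, kind):
    return x.relu() if kind == "relu" else x.hardswish()


class MBConv(nn.Module):
    """MobileNetV3 bottleneck: 1×1 expand → 3×3 depthwise → SE → 1×1 project,
    residual when stride 1 and matching widths.  Batch normalization (the
    backbone's native norm) follows each convolution: unlike instance norm
    it preserves the cross-sample channel-mean differences — global stain
    density and tint — that carry the HER2 signal."""

    def __init__(self, cin, spec: BlockSpec, *, rng):
        self.spec = spec
        self.expand = (nn.Conv2d(cin, spec.exp, 1, init="he", rng=rng)
                       if spec.exp != cin else None)
        self.n1 = nn.BatchNorm2d(spec.exp) if self.expand is not None else None
        self.dw = nn.DepthwiseConv2d(spec.exp, 3, stride=spec.stride, init="he", rng=rng)
        self.n2 = nn.BatchNorm2d(spec.exp)
        self.se = SqueezeExcite(spec.exp, rng=rng) if spec.se else None
        self.project = nn.Conv2d(spec.exp, spec.out, 1, init="he", rng=rng)
        self.n3 = nn.BatchNorm2d(spec.out)
        self.skip = spec.stride == 1 and cin == spec.out

    def forward(self, x):
        h = x
        if self.expand is not None:
            h = _act(self.n1(self.expand(h)), self.spec.act)
        h = _act(self.n2(self.dw(h)), self.spec.act)
        if self.se is not None:
            h = self.se(h)
        h = self.n3(self.project(h))
        return h + x if self.skip else h


class Her2Classifier(nn.Module):
    def __init__(self, cfg: ClassifierConfig = ClassifierConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stem = nn.Conv2d(3, cfg.stem, 3, stride=2, init="he", rng=rng)
        self.stem_norm = nn.BatchNorm2d(cfg.stem)
        blocks, cin = [], cfg.stem
        for spec in cfg.blocks:
            blocks.append(MBConv(cin, spec, rng=rng))
            cin = spec.out
        self.blocks = blocks
        self.head_conv = nn.Conv2d(cin, cfg.head_conv, 1, init="he", rng=rng)
        self.head_norm = nn.BatchNorm2d(cfg.head_conv)
        self.fc1 = nn.Linear(cfg.head_conv, cfg.head_hidden, init="he", rng=rng)
        self.fc2 = nn.Linear(cfg.head_hidden, cfg.n_classes, init="he", rng=rng)

    def forward(self, x: nn.Tensor):
        """Returns (logits, taps, penultimate)."""
        cfg = self.cfg
        h = self.stem_norm(self.stem(x)).hardswish()
        taps = {}
        for i, block in enumerate(self.blocks):
            h = block(h)
            if i == cfg.tap8_index:
                taps["s8"] = h
            elif i == cfg.tap16_index:
                taps["s16"] = h
        h = self.head_norm(self.head_conv(h)).hardswish()
        pooled = F.global_avg_pool(h)
        penult = self.fc1(pooled).hardswish()
        logits = self.fc2(penult)
        return logits, taps, penult


# --------------------------------------------------------------------- api

def _to_nchw(images: list[Image]) -> np.ndarray:
    for img in images:
        if img.range != "norm":
            raise ValueError("classifier expects normalized ([-1,1]) inputs")
    return np.stack([img.data.transpose(2, 0, 1) for img in images])


def classify(model: Her2Classifier, images: list[Image] | Image) -> ClassifierOutput:
    """Score normalized H&E images; input side must be divisible by 32."""
    if isinstance(images, Image):
        images = [images]
    x = _to_nchw(images)
    if x.shape[2] % 32 or x.shape[2] != x.shape[3]:
        raise ValueError(f"input side must be square and divisible by 32, got {x.shape[2:]}")
    was_training = model.training
    model.eval()
    logits, taps, penult = model(nn.Tensor(x))
    model.train(was_training)
    probs = F.softmax(logits.data, axis=1)
    predicted = [Her2Level(int(i)) for i in probs.argmax(axis=1)]
    return ClassifierOutput(probs, predicted, taps, penult.data)


@dataclass
class EpochStats:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float


def _manifest_arrays(manifest: Manifest, side: int):
    xs, ys = [], []
    for ref in manifest.pairs:
        pair = load_manifest_pair(ref)
        he = normalize(resize_to(pair.he, side))
        xs.append(he.data.transpose(2, 0, 1))
        ys.append(ref.level.index)
    return np.stack(xs), np.asarray(ys, np.int64)


def _geo(img_chw: np.ndarray, rng) -> np.ndarray:
    """One of the 12 rotation/flip transforms, drawn from ``rng``."""
    rot = int(rng.integers(4))
    flip = int(rng.integers(3))
    out = np.rot90(img_chw, k=rot, axes=(1, 2))
    if flip == 1:
        out = out[:, :, ::-1]
    elif flip == 2:
        out = out[:, ::-1, :]
    return np.ascontiguousarray(out)


def _eval(model, x, y, batch: int = 16):
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        logits, _, _ = model(nn.Tensor(x[i:i + batch]))
        losses.append(F.cross_entropy(logits, y[i:i + batch]).item() * len(logits.data))
        correct += int((logits.data.argmax(axis=1) == y[i:i + batch]).sum())
    return sum(losses) / len(x), correct / len(x)


def finetune(model: Her2Classifier, train: Manifest, val: Manifest, epochs: int,
             seed: int, side: int = 64, lr: float = 1e-3, batch_size: int = 16,
             augment: bool = True):
    """Cross-entropy finetuning with rotation/flip augmentation; returns
    (per-epoch stats, best-val weights)."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val manifests must be non-empty")
    xt, yt = _manifest_arrays(train, side)
    xv, yv = _manifest_arrays(val, side)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr, betas=(0.9, 0.999))
    record, best = [], (None, -1.0)
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(xt))
        losses, correct = [], 0
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            xb = xt[idx]
            if augment:
                xb = np.stack([_geo(img, rng) for img in xb])
            logits, _, _ = model(nn.Tensor(xb))
            loss = F.cross_entropy(logits, yt[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(idx))
            correct += int((logits.data.argmax(axis=1) == yt[idx]).sum())
        val_loss, val_acc = _eval(model, xv, yv)
        record.append(EpochStats(epoch, sum(losses) / len(xt), correct / len(xt),
                                 val_loss, val_acc))
        if val_acc > best[1]:
            best = (model.state_dict(), val_acc)
    if best[0] is not None:
        model.load_state_dict(best[0])
    return record, best[0]
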