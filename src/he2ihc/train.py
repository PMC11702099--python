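"""Alternating generator/discriminator optimization.

One discriminator step (real pair vs. detached fake, for both the
full-resolution pair and the upsampled low-resolution pair, through the
same three-scale ensemble) followed by one generator step on the weighted
total objective.  Fully seeded: parameter initialization, shuffling and
augmentation draws all derive from the run seed.  Emits per-epoch loss
curves (CSV) and latest/best checkpoints.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F
from .classifier import Her2Classifier
from .discriminator import MultiScaleDiscriminator
from .features import default_extractor
from .generator import DualScaleGenerator, GeneratorOutput
from .losses import (
    LossBreakdown, LossWeights, adversarial_loss, feature_matching_loss,
    l1_loss, perceptual_loss, total_loss,
)
from .metrics import psnr as psnr_metric, ssim as ssim_metric
from .stain_io import (
    Her2Level, Image, Manifest, NORM, StainPair, augment, load_manifest_pair,
    normalize, resize_to,
)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200               # the full-scale training length
    batch_size: int = 4
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    side: int = 256
    gan_mode: str = "vanilla"
    augment: bool = True
    log_every: int = 50
    checkpoint_every: int = 10      # epochs

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or min(self.lr_g, self.lr_d) < 0:
            raise ValueError("epochs/batch_size must be >= 1 and learning rates >= 0")


@dataclass
class EpochRecord:
    epoch: int
    g_train: float
    g_val: float
    d_train: float
    d_val: float
    val_psnr: float
    val_ssim: float


def _pairs_to_arrays(pairs: list[StainPair], side: int):
    he, ihc, levels = [], [], []
    for p in pairs:
        h = normalize(resize_to(p.he, side)) if p.he.range != NORM else p.he
        i = normalize(resize_to(p.ihc, side)) if p.ihc.range != NORM else p.ihc
        he.append(h.data.transpose(2, 0, 1))
        ihc.append(i.data.transpose(2, 0, 1))
        levels.append(p.level)
    return np.stack(he), np.stack(ihc), levels


def load_training_arrays(manifest: Manifest, side: int):
    return _pairs_to_arrays([load_manifest_pair(r) for r in manifest.pairs], side)


@dataclass
class TrainState:
    """Bundle of networks and optimizers for one run."""

    generator: DualScaleGenerator
    discriminator: MultiScaleDiscriminator
    classifier: Her2Classifier | None
    opt_g: nn.Adam
    opt_d: nn.Adam
    extractor: object

    @classmethod
    def create(cls, generator, discriminator, classifier, cfg: TrainConfig):
        if classifier is not None:
            classifier.eval()  # frozen guidance network: inference statistics
        return cls(
            generator, discriminator, classifier,
            nn.Adam(generator.parameters(), lr=cfg.lr_g, betas=cfg.adam_betas),
            nn.Adam(discriminator.parameters(), lr=cfg.lr_d, betas=cfg.adam_betas),
            default_extractor(),
        )


def _taps_for(classifier, x: Tensor):
    if classifier is None:
        return None
    _, taps, _ = classifier(x)
    return {k: v.detach() for k, v in taps.items()}


def _full_and_low(state: TrainState, x: Tensor, y: Tensor, levels):
    out: GeneratorOutput = state.generator.generate(x, levels, _taps_for(state.classifier, x))
    side = x.shape[2]
    y_s = F.bilinear_resize(y, side // 4)
    # low pair rides through the same discriminators at full side
    low_real = F.bilinear_resize(y_s, side)
    low_fake = F.bilinear_resize(out.low_fake, side)
    low_x = F.bilinear_resize(out.low_input, side)
    return out, low_x, low_real, low_fake


def train_step(state: TrainState, batch_x: np.ndarray, batch_y: np.ndarray,
               levels, w: LossWeights, gan_mode: str = "vanilla") -> LossBreakdown:
    """One D update then one G update on a batch; returns the breakdown."""
    x, y = Tensor(batch_x), Tensor(batch_y)
    out, low_x, low_real, low_fake = _full_and_low(state, x, y, levels)

    # ---- discriminator step (fakes detached)
    d = state.discriminator
    real_taps = d.discriminate(x, y)
    fake_taps_d = d.discriminate(x, out.full.detach())
    low_real_taps = d.discriminate(low_x.detach(), low_real.detach())
    low_fake_taps_d = d.discriminate(low_x.detach(), low_fake.detach())
    gan_d_full, _ = adversarial_loss(real_taps, fake_taps_d, gan_mode)
    gan_d_low, _ = adversarial_loss(low_real_taps, low_fake_taps_d, gan_mode)
    gan_d = 0.5 * (gan_d_full + gan_d_low)
    state.opt_d.zero_grad()
    gan_d.backward()
    state.opt_d.step()

    # ---- generator step
    fake_taps = d.discriminate(x, out.full)
    low_fake_taps = d.discriminate(low_x.detach(), low_fake)
    _, gan_g_full = adversarial_loss(real_taps, fake_taps, gan_mode)
    _, gan_g_low = adversarial_loss(low_real_taps, low_fake_taps, gan_mode)
    gan_g = 0.5 * (gan_g_full + gan_g_low)
    fm = feature_matching_loss(real_taps, fake_taps, low_real_taps, low_fake_taps)
    vgg = perceptual_loss(y, out.full, state.extractor)
    l1 = l1_loss(y, out.full)
    total, breakdown = total_loss(gan_g, fm, vgg, l1, w, gan_d)
    state.opt_g.zero_grad()
    state.discriminator.zero_grad()
    total.backward()
    state.opt_g.step()
    return breakdown


def evaluate(state: TrainState, val_x: np.ndarray, val_y: np.ndarray, levels,
             w: LossWeights, gan_mode: str = "vanilla", batch: int = 4):
    """Validation losses plus raw8 PSNR/SSIM of G(x) against y."""
    g_losses, d_losses, psnrs, ssims = [], [], [], []
    for i in range(0, len(val_x), batch):
        x, y = Tensor(val_x[i:i + batch]), Tensor(val_y[i:i + batch])
        lv = levels[i:i + batch]
        out, low_x, low_real, low_fake = _full_and_low(state, x, y, lv)
        real_taps = state.discriminator.discriminate(x, y)
        fake_taps = state.discriminator.discriminate(x, out.full)
        low_real_taps = state.discriminator.discriminate(low_x, low_real)
        low_fake_taps = state.discriminator.discriminate(low_x, low_fake)
        gan_d_f, gan_g_f = adversarial_loss(real_taps, fake_taps, gan_mode)
        gan_d_l, gan_g_l = adversarial_loss(low_real_taps, low_fake_taps, gan_mode)
        fm = feature_matching_loss(real_taps, fake_taps, low_real_taps, low_fake_taps)
        vgg = perceptual_loss(y, out.full, state.extractor)
        l1 = l1_loss(y, out.full)
        _, br = total_loss(0.5 * (gan_g_f + gan_g_l), fm, vgg, l1, w,
                           0.5 * (gan_d_f + gan_d_l))
        g_losses.append(br.total_g)
        d_losses.append(br.gan_d)
        fake8 = np.clip((out.full.data.transpose(0, 2, 3, 1) + 1) * 127.5, 0, 255)
        real8 = np.clip((y.data.transpose(0, 2, 3, 1) + 1) * 127.5, 0, 255)
        for j in range(len(fake8)):
            pv, _ = psnr_metric(real8[j], fake8[j])
            psnrs.append(min(pv, 99.0))
            ssims.append(ssim_metric(real8[j], fake8[j]))
    return (float(np.mean(g_losses)), float(np.mean(d_losses)),
            float(np.mean(psnrs)), float(np.mean(ssims)))


def save_checkpoint(path, state: TrainState, cfg: TrainConfig | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for prefix, net in (("g", state.generator), ("d", state.discriminator),
                        ("c", state.classifier)):
        if net is None:
            continue
        for k, v in net.state_dict().items():
            arrays[f"{prefix}::{k}"] = v
    np.savez(path, **arrays)
    if cfg is not None:
        meta = asdict(cfg)
        meta["weights"] = asdict(cfg.weights)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path, generator, discriminator, classifier=None) -> None:
    with np.load(path) as data:
        split = {"g": {}, "d": {}, "c": {}}
        for key in data.files:
            prefix, name = key.split("::", 1)
            split[prefix][name] = data[key]
    generator.load_state_dict(split["g"])
    discriminator.load_state_dict(split["d"])
    if classifier is not None and split["c"]:
        classifier.load_state_dict(split["c"])


def fit(train_manifest: Manifest, val_manifest: Manifest, cfg: TrainConfig,
        generator: DualScaleGenerator, discriminator: MultiScaleDiscriminator,
        classifier: Her2Classifier | None = None,
        workdir=None, train_pairs: list[StainPair] | None = None,
        val_pairs: list[StainPair] | None = None) -> list[EpochRecord]:
    """Run the training loop; returns per-epoch records.

    Pairs may be supplied directly (``train_pairs``/``val_pairs``) to bypass
    disk I/O; otherwise they are loaded through the manifests.
    """
    if train_pairs is None:
        if train_manifest is None or len(train_manifest) == 0:
            raise ValueError("empty training manifest")
        train_pairs = [load_manifest_pair(r) for r in train_manifest.pairs]
    if val_pairs is None:
        if val_manifest is None or len(val_manifest) == 0:
            raise ValueError("empty validation manifest")
        val_pairs = [load_manifest_pair(r) for r in val_manifest.pairs]

    rng = np.random.default_rng(cfg.seed)
    state = TrainState.create(generator, discriminator, classifier, cfg)
    val_x, val_y, val_levels = _pairs_to_arrays(val_pairs, cfg.side)

    workdir = Path(workdir) if workdir is not None else None
    records: list[EpochRecord] = []
    best_psnr = -np.inf
    curve_path = workdir / "curves.csv" if workdir else None
    if curve_path:
        workdir.mkdir(parents=True, exist_ok=True)
        with open(curve_path, "w", newline="") as fh:
            csv.writer(fh).writerow(
                ["epoch", "g_train", "g_val", "d_train", "d_val", "val_psnr", "val_ssim"])

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        g_losses, d_losses = [], []
        for i in range(0, len(order), cfg.batch_size):
            chunk = [train_pairs[j] for j in order[i:i + cfg.batch_size]]
            if cfg.augment:
                chunk = [augment(p, int(rng.integers(2 ** 31))) for p in chunk]
            bx, by, lv = _pairs_to_arrays(chunk, cfg.side)
            br = train_step(state, bx, by, lv, cfg.weights, cfg.gan_mode)
            g_losses.append(br.total_g)
            d_losses.append(br.gan_d)
        g_val, d_val, v_psnr, v_ssim = evaluate(
            state, val_x, val_y, val_levels, cfg.weights, cfg.gan_mode)
        rec = EpochRecord(epoch, float(np.mean(g_losses)), g_val,
                          float(np.mean(d_losses)), d_val, v_psnr, v_ssim)
        records.append(rec)
        if curve_path:
            with open(curve_path, "a", newline="") as fh:
                csv.writer(fh).writerow(
                    [rec.epoch, rec.g_train, rec.g_val, rec.d_train, rec.d_val,
                     rec.val_psnr, rec.val_ssim])
        if workdir:
            latest = workdir / "latest.npz"
            if (epoch + 1) % cfg.checkpoint_every == 0 or epoch == cfg.epochs - 1:
                save_checkpoint(latest, state, cfg)
            if v_psnr > best_psnr:
                best_psnr = v_psnr
                save_checkpoint(workdir / "best.npz", state, cfg)
    return records
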