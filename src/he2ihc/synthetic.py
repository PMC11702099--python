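"""Class-conditional synthetic pseudo-H&E / pseudo-IHC pair generator.

Every pair is produced by a *known deterministic mapping*: the pseudo-IHC
target is an exact function ``stain_transform(he, level)`` of the stored
pseudo-H&E image and the HER2 level, so supervised translation loss can in
principle be driven to zero and every downstream stage is testable without
any external dataset.

Construction: a Gaussian-smoothed white-noise field is thresholded at a
fixed quantile into a "nucleus" mask; a dilated ring around it plays the
cell-membrane compartment where DAB chromogen accumulates. The pseudo-H&E
image is a pink background with purple nuclei plus low-amplitude pixel
noise; the pseudo-IHC recolors nuclei to hematoxylin blue and blends the
membrane ring toward DAB brown with a strictly level-increasing gain.

The pseudo-H&E itself is level-dependent — nucleus density and background
tint shift monotonically with HER2 level — emulating the real correlation
of H&E morphology with HER2 status that makes an H&E-only HER2 classifier
meaningful in the first place.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .stain_io import (
    RAW8, Her2Level, Image, Manifest, PairRef, StainPair, write_image,
)

# raw8 palette; chosen so brown-channel excess (R+G)/2 - B is <= 0 everywhere
# at gain 0 and strictly increases with the DAB gain on ring pixels
HE_BACKGROUND = np.array([235, 185, 210], np.float32)   # eosin pink
HE_NUCLEUS = np.array([90, 50, 140], np.float32)        # hematoxylin purple
IHC_BACKGROUND = np.array([236, 236, 240], np.float32)  # unstained tissue
IHC_NUCLEUS = np.array([70, 80, 165], np.float32)       # hematoxylin blue
DAB_BROWN = np.array([150, 90, 30], np.float32)         # chromogen

# pixels with green channel below this are "nuclei" when re-deriving the
# masks from a stored pseudo-H&E image (purple G≈50 vs pink G≈185; robust
# to the <=5/255 noise amplitude)
_NUCLEUS_G_THRESHOLD = 100.0
_RING_ITERATIONS = 2


@dataclass(frozen=True)
class SynthConfig:
    """Conditions of the synthetic stain-translation task."""

    side: int = 64
    n_per_class: int = 50
    seed: int = 0
    blob_density: float = 0.22
    density_step: float = 0.08  # tumor cellularity grows with HER2 level, so
                                # the class is recoverable from the H&E input
    tint_step: tuple = (-12.0, -9.0, 7.0)  # per-level RGB shift of the H&E
                                # background: higher-grade tissue reads
                                # subtly bluer/less eosinophilic
    dab_gain: tuple = (0.0, 0.25, 0.55, 0.9)
    noise_amp: int = 4          # raw8 counts, <= 5 so masks re-derive exactly
    blob_sigma: float = 3.0

    def __post_init__(self):
        if self.side < 16:
            raise ValueError("side must be >= 16")
        if not 0 < self.blob_density < 1:
            raise ValueError("blob_density must lie in (0, 1)")
        if not 0 < self.blob_density + 3 * self.density_step < 1:
            raise ValueError("blob_density + 3*density_step must lie in (0, 1)")
        g = self.dab_gain
        if not (g[0] < g[1] < g[2] < g[3]):
            raise ValueError(f"dab_gain must be strictly increasing, got {g}")


def _nucleus_mask_from_he(he_raw8: np.ndarray) -> np.ndarray:
    return he_raw8[:, :, 1] < _NUCLEUS_G_THRESHOLD


def _ring_mask(nucleus: np.ndarray) -> np.ndarray:
    dilated = binary_dilation(nucleus, iterations=_RING_ITERATIONS)
    return dilated & ~nucleus


def stain_transform(he_raw8: np.ndarray, level: Her2Level, cfg: SynthConfig) -> np.ndarray:
    """The ground-truth H&E→IHC mapping T_level: a deterministic recoloring
    of the pseudo-H&E image driven only by its pixel classes and the level."""
    he_raw8 = np.asarray(he_raw8)
    nucleus = _nucleus_mask_from_he(he_raw8.astype(np.float32))
    ring = _ring_mask(nucleus)
    gain = float(cfg.dab_gain[level.index])
    out = np.empty(he_raw8.shape[:2] + (3,), np.float32)
    out[:] = IHC_BACKGROUND
    out[nucleus] = IHC_NUCLEUS
    out[ring] = np.round((1.0 - gain) * IHC_BACKGROUND + gain * DAB_BROWN)
    return np.round(out).astype(np.uint8)


def make_pair(level: Her2Level, cfg: SynthConfig, draw: int) -> StainPair:
    """Deterministic in (level, cfg.seed, draw)."""
    rng = np.random.default_rng([cfg.seed, level.index, draw])
    noise = rng.normal(size=(cfg.side, cfg.side))
    smooth = gaussian_filter(noise, cfg.blob_sigma)
    density = cfg.blob_density + cfg.density_step * level.index
    threshold = np.quantile(smooth, 1.0 - density)
    nucleus = smooth > threshold

    he = np.empty((cfg.side, cfg.side, 3), np.float32)
    he[:] = HE_BACKGROUND + level.index * np.asarray(cfg.tint_step, np.float32)
    he[nucleus] = HE_NUCLEUS
    if cfg.noise_amp > 0:
        jitter = rng.integers(-cfg.noise_amp, cfg.noise_amp + 1,
                              size=he.shape).astype(np.float32)
        he = np.clip(he + jitter, 0, 255)
    he_u8 = he.astype(np.uint8)
    ihc_u8 = stain_transform(he_u8, level, cfg)
    pair_id = f"syn{draw:04d}_{level.index}"
    return StainPair(Image(he_u8, RAW8), Image(ihc_u8, RAW8), level, pair_id)


def make_pairs(cfg: SynthConfig) -> list[StainPair]:
    """All 4 * n_per_class pairs, in (draw, level) order, fully in memory."""
    return [
        make_pair(Her2Level(lvl), cfg, draw)
        for draw in range(cfg.n_per_class)
        for lvl in range(4)
    ]


def make_dataset(cfg: SynthConfig, root) -> Manifest:
    """Write the balanced synthetic dataset in the BCI-style tree layout."""
    root = Path(root)
    he_dir, ihc_dir = root / "HE", root / "IHC"
    try:
        he_dir.mkdir(parents=True, exist_ok=True)
        ihc_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset tree under {root}: {exc}") from exc
    refs = []
    with open(root / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "level"])
        for pair in make_pairs(cfg):
            he_path = he_dir / f"{pair.pair_id}.png"
            ihc_path = ihc_dir / f"{pair.pair_id}.png"
            write_image(pair.he, he_path)
            write_image(pair.ihc, ihc_path)
            writer.writerow([pair.pair_id, pair.level.label])
            refs.append(PairRef(pair.pair_id, str(he_path), str(ihc_path), pair.level))
    manifest = Manifest(refs, str(root))
    manifest.validate()
    return manifest


def brown_excess(ihc_raw8: np.ndarray) -> float:
    """Mean positive excess of the warm channels over blue — the image-level
    DAB signal the linear class probe keys on."""
    arr = np.asarray(ihc_raw8, np.float32)
    return float(np.mean(np.maximum((arr[:, :, 0] + arr[:, :, 1]) / 2.0 - arr[:, :, 2], 0.0)))
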