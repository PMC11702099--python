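"""Paired-stain dataset I/O: loading, normalization, resizing, augmentation
and stratified splitting of registered H&E/IHC image pairs.

Dataset layout (BCI-style)::

    <root>/HE/<pair_id>.<ext>
    <root>/IHC/<pair_id>.<ext>
    <root>/labels.csv            # pair_id,level   (or a _<level> filename suffix)

Images are held channel-last (H, W, 3) float32 with an explicit range tag:
``raw8`` for [0, 255] and ``norm`` for [-1, 1].
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from skimage.transform import resize as _sk_resize

RAW8 = "raw8"
NORM = "norm"

LEVELS = ("0", "1+", "2+", "3+")


@dataclass(frozen=True)
class Her2Level:
    """HER2 expression level: one of 0, 1+, 2+, 3+ (index 0-3)."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index <= 3:
            raise ValueError(f"HER2 level index out of range: {self.index}")

    @property
    def label(self) -> str:
        return LEVELS[self.index]

    @classmethod
    def from_label(cls, label: str) -> "Her2Level":
        label = str(label).strip()
        if label in LEVELS:
            return cls(LEVELS.index(label))
        if label.isdigit() and 0 <= int(label) <= 3:
            return cls(int(label))
        raise ValueError(f"unknown HER2 level {label!r}; expected one of {LEVELS}")


@dataclass
class Image:
    """An RGB image with a declared value-range tag."""

    data: np.ndarray          # (H, W, 3) float32
    range: str = RAW8

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = np.repeat(self.data[:, :, None], 3, axis=2)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) image, got {self.data.shape}")
        if self.range not in (RAW8, NORM):
            raise ValueError(f"unknown range tag {self.range!r}")

    @property
    def side(self) -> int:
        return self.data.shape[0]


@dataclass
class StainPair:
    """A registered (H&E input, IHC target) pair with its HER2 level."""

    he: Image
    ihc: Image
    level: Her2Level
    pair_id: str = ""

    def __post_init__(self):
        if self.he.data.shape != self.ihc.data.shape:
            raise ValueError(
                f"pairing error: H&E shape {self.he.data.shape} != IHC shape {self.ihc.data.shape}"
            )
        if self.he.range != self.ihc.range:
            raise ValueError("pairing error: H&E and IHC range tags differ")


@dataclass(frozen=True)
class PairRef:
    pair_id: str
    he_path: str
    ihc_path: str
    level: Her2Level


@dataclass
class Manifest:
    """Ordered list of stain-pair references rooted at a dataset directory."""

    pairs: list[PairRef] = field(default_factory=list)
    root: str = ""

    def __len__(self):
        return len(self.pairs)

    def validate(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pair_ids in manifest")
        for p in self.pairs:
            for path in (p.he_path, p.ihc_path):
                if not Path(path).exists():
                    raise FileNotFoundError(f"manifest references missing file: {path}")

    def to_json(self) -> dict:
        return {
            "root": self.root,
            "pairs": [
                {"pair_id": p.pair_id, "he": p.he_path, "ihc": p.ihc_path, "level": p.level.label}
                for p in self.pairs
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Manifest":
        return cls(
            pairs=[
                PairRef(d["pair_id"], d["he"], d["ihc"], Her2Level.from_label(d["level"]))
                for d in obj["pairs"]
            ],
            root=obj.get("root", ""),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path) -> "Manifest":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions (must sum to 1) plus the shuffle seed."""

    fractions: tuple = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(f < 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must be non-negative and sum to 1: {self.fractions}")


# --------------------------------------------------------------------- loading

def read_image(path) -> Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with PILImage.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
    return Image(arr, RAW8)


def write_image(img: Image, path) -> None:
    if img.range != RAW8:
        img = denormalize(img)
    arr = np.clip(np.round(img.data), 0, 255).astype(np.uint8)
    PILImage.fromarray(arr).save(path)


def load_pair(he_path, ihc_path, level: Her2Level, pair_id: str = "") -> StainPair:
    """Read a registered pair from disk; dimensions must match exactly."""
    he = read_image(he_path)
    ihc = read_image(ihc_path)
    if not pair_id:
        pair_id = Path(he_path).stem
    return StainPair(he, ihc, level, pair_id)


def build_manifest(root) -> Manifest:
    """Discover a BCI-style tree; levels from labels.csv or a _<level> suffix."""
    root = Path(root)
    he_dir, ihc_dir = root / "HE", root / "IHC"
    if not he_dir.is_dir() or not ihc_dir.is_dir():
        raise FileNotFoundError(f"expected HE/ and IHC/ under {root}")
    labels: dict[str, Her2Level] = {}
    csv_path = root / "labels.csv"
    if csv_path.exists():
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                labels[row["pair_id"]] = Her2Level.from_label(row["level"])
    pairs = []
    for he_path in sorted(he_dir.iterdir()):
        if he_path.suffix.lower() not in (".png", ".tif", ".tiff", ".jpg", ".jpeg"):
            continue
        pid = he_path.stem
        ihc_path = ihc_dir / he_path.name
        if not ihc_path.exists():
            raise FileNotFoundError(f"pairing error: no IHC counterpart for {he_path.name}")
        if pid in labels:
            lvl = labels[pid]
        else:
            suffix = pid.rsplit("_", 1)[-1]
            lvl = Her2Level.from_label(suffix)
        pairs.append(PairRef(pid, str(he_path), str(ihc_path), lvl))
    m = Manifest(pairs, str(root))
    m.validate()
    return m


def load_manifest_pair(ref: PairRef) -> StainPair:
    return load_pair(ref.he_path, ref.ihc_path, ref.level, ref.pair_id)


# ----------------------------------------------------------------- transforms

def normalize(img: Image) -> Image:
    """Map raw8 pixel values into [-1, 1] via v/127.5 - 1."""
    if img.range != RAW8:
        raise ValueError(f"normalize expects a raw8 image, got range tag {img.range!r}")
    return Image(img.data / 127.5 - 1.0, NORM)


def denormalize(img: Image) -> Image:
    """Inverse of :func:`normalize`; clips to [0, 255]."""
    if img.range != NORM:
        raise ValueError(f"denormalize expects a norm image, got range tag {img.range!r}")
    return Image(np.clip((img.data + 1.0) * 127.5, 0.0, 255.0), RAW8)


def resize_to(img: Image, side: int) -> Image:
    """Bilinear resize to side×side (anti-aliased when downscaling)."""
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    h, w = img.data.shape[:2]
    if (h, w) == (side, side):
        return Image(img.data.copy(), img.range)
    out = _sk_resize(
        img.data, (side, side), order=1, anti_aliasing=(side < min(h, w)),
        preserve_range=True, mode="edge",
    ).astype(np.float32)
    return Image(out, img.range)


# 12 registration-preserving transforms: 4 rotations × 3 flip states
_TRANSFORMS = [(r, f) for r in range(4) for f in ("none", "h", "v")]


def _apply_geo(arr: np.ndarray, rot: int, flip: str) -> np.ndarray:
    out = np.rot90(arr, k=rot, axes=(0, 1))
    if flip == "h":
        out = out[:, ::-1]
    elif flip == "v":
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment(pair: StainPair, seed: int) -> StainPair:
    """Draw one of the 12 rotation/flip transforms and apply it identically
    to both members of the pair, preserving registration."""
    if pair.he.side != pair.he.data.shape[1]:
        raise ValueError("augment requires square images")
    rng = np.random.default_rng(seed)
    rot, flip = _TRANSFORMS[int(rng.integers(len(_TRANSFORMS)))]
    return StainPair(
        Image(_apply_geo(pair.he.data, rot, flip), pair.he.range),
        Image(_apply_geo(pair.ihc.data, rot, flip), pair.ihc.range),
        pair.level,
        pair.pair_id,
    )


# -------------------------------------------------------------------- splits

def split_manifest(m: Manifest, spec: SplitSpec) -> tuple[Manifest, Manifest, Manifest]:
    """Stratified (per HER2 level) shuffle-split into train/val/test.

    Val and test take floor(n·fraction) pairs per level; train receives the
    rounding remainder, so the three parts are disjoint and exhaustive.
    """
    if len(m) == 0:
        raise ValueError("cannot split an empty manifest")
    rng = np.random.default_rng(spec.seed)
    f_train, f_val, f_test = spec.fractions
    out = {"train": [], "val": [], "test": []}
    for lvl in range(4):
        group = [p for p in m.pairs if p.level.index == lvl]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        n = len(group)
        n_val = int(np.floor(n * f_val))
        n_test = int(np.floor(n * f_test))
        out["val"].extend(group[:n_val])
        out["test"].extend(group[n_val:n_val + n_test])
        out["train"].extend(group[n_val + n_test:])
    return tuple(Manifest(out[k], m.root) for k in ("train", "val", "test"))
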