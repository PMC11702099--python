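"""Image-quality evaluation suite: SSIM, PSNR/MSE, cosine similarity,
Euclidean distance, FID, LPIPS, deep-feature similarity, and per-channel
pixel-distribution comparison.

Pixel metrics operate on 8-bit-range (raw8) images with maxval 255; SSIM is
computed on the BT.601 luma channel with the standard 11×11 Gaussian window
(σ = 1.5) and constants K1 = 0.01, K2 = 0.03, C3 = C2/2, exponents
α = β = γ = 1 by default.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import sqrtm as _sqrtm
from scipy.signal import fftconvolve

from .nn import Tensor
from .stain_io import Image, RAW8, read_image

PSNR_IDENTICAL = math.inf  # sentinel for zero-MSE comparisons


# ------------------------------------------------------------------- SSIM

@dataclass(frozen=True)
class SsimParams:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0
    window: int = 11
    sigma: float = 1.5

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) <= 0:
            raise ValueError("SSIM exponents must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0


def _luma(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        return 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return arr.astype(np.float64)


def gaussian_window(side: int, sigma: float) -> np.ndarray:
    ax = np.arange(side) - (side - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(a: Image | np.ndarray, b: Image | np.ndarray,
         p: SsimParams = SsimParams()) -> float:
    """Mean over valid Gaussian windows of l^α · c^β · s^γ."""
    xa = _as_raw8_array(a).astype(np.float64)
    xb = _as_raw8_array(b).astype(np.float64)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {xb.shape}")
    x, y = _luma(xa), _luma(xb)
    if min(x.shape) < p.window:
        raise ValueError(f"image smaller than the {p.window}×{p.window} SSIM window")
    w = gaussian_window(p.window, p.sigma)
    mu_x = fftconvolve(x, w, mode="valid")
    mu_y = fftconvolve(y, w, mode="valid")
    exx = fftconvolve(x * x, w, mode="valid")
    eyy = fftconvolve(y * y, w, mode="valid")
    exy = fftconvolve(x * y, w, mode="valid")
    var_x = np.maximum(exx - mu_x ** 2, 0.0)
    var_y = np.maximum(eyy - mu_y ** 2, 0.0)
    cov = exy - mu_x * mu_y
    sx, sy = np.sqrt(var_x), np.sqrt(var_y)
    l = (2 * mu_x * mu_y + p.c1) / (mu_x ** 2 + mu_y ** 2 + p.c1)
    c = (2 * sx * sy + p.c2) / (var_x + var_y + p.c2)
    s = (cov + p.c3) / (sx * sy + p.c3)
    smap = np.sign(l) * np.abs(l) ** p.alpha
    smap = smap * (np.sign(c) * np.abs(c) ** p.beta)
    smap = smap * (np.sign(s) * np.abs(s) ** p.gamma)
    return float(smap.mean())


# -------------------------------------------------------------- PSNR / MSE

def psnr(a: Image | np.ndarray, b: Image | np.ndarray,
         maxval: float = 255.0) -> tuple[float, float]:
    """Returns (psnr_dB, mse); identical inputs yield (inf, 0)."""
    xa = _as_raw8_array(a).astype(np.float64)
    xb = _as_raw8_array(b).astype(np.float64)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch: {xa.shape} vs {xb.shape}")
    mse = float(np.mean((xa - xb) ** 2))
    if mse == 0.0:
        return PSNR_IDENTICAL, 0.0
    return 10.0 * math.log10(maxval ** 2 / mse), mse


# ------------------------------------------------------- vector similarities

def cosine_similarity(r: np.ndarray, g: np.ndarray) -> float:
    r = np.asarray(r, np.float64).ravel()
    g = np.asarray(g, np.float64).ravel()
    if r.shape != g.shape:
        raise ValueError(f"length mismatch: {r.shape} vs {g.shape}")
    nr, ng = np.linalg.norm(r), np.linalg.norm(g)
    if nr == 0.0 and ng == 0.0:
        raise ValueError("cosine similarity undefined for two zero vectors")
    if nr == 0.0 or ng == 0.0:
        return 0.0
    return float(np.dot(r, g) / (nr * ng))


def euclidean_distance(r: np.ndarray, g: np.ndarray) -> float:
    r = np.asarray(r, np.float64).ravel()
    g = np.asarray(g, np.float64).ravel()
    if r.shape != g.shape:
        raise ValueError(f"length mismatch: {r.shape} vs {g.shape}")
    return float(np.sqrt(np.sum((r - g) ** 2)))


# --------------------------------------------------------------------- FID

@dataclass
class GaussianStats:
    mean: np.ndarray
    cov: np.ndarray
    n: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, np.float64).ravel()
        self.cov = np.asarray(self.cov, np.float64)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match mean dimension")
        if self.n < 2:
            raise ValueError("need n >= 2 samples for covariance statistics")


def gaussian_stats(features: np.ndarray) -> GaussianStats:
    features = np.asarray(features, np.float64)
    return GaussianStats(features.mean(axis=0), np.cov(features, rowvar=False), len(features))


def fid(real: GaussianStats, fake: GaussianStats, psd_tol: float = 1e-6) -> float:
    """Fréchet distance between the two Gaussian feature fits."""
    if real.mean.size != fake.mean.size:
        raise ValueError("feature dimensionality mismatch")
    for s in (real, fake):
        ev_min = float(np.linalg.eigvalsh((s.cov + s.cov.T) / 2).min())
        scale = max(1.0, float(np.abs(s.cov).max()))
        if ev_min < -psd_tol * scale:
            raise np.linalg.LinAlgError(
                f"covariance not PSD within tolerance (min eigenvalue {ev_min:.3e})"
            )
    diff = real.mean - fake.mean
    covmean = _sqrtm(real.cov @ fake.cov)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    value = float(diff @ diff + np.trace(real.cov + fake.cov - 2.0 * covmean))
    return max(value, 0.0)


# -------------------------------------------------------------------- LPIPS

def lpips(a: Image | np.ndarray, b: Image | np.ndarray, extractor,
          linear_weights) -> float:
    """Channel-normalized, linearly-weighted squared deep-feature distance."""
    xa, xb = _to_norm_nchw(a), _to_norm_nchw(b)
    fa = extractor(Tensor(xa))
    fb = extractor(Tensor(xb))
    weights = getattr(linear_weights, "per_layer", linear_weights)
    if len(weights) != len(fa):
        raise ValueError("need one weight vector per extractor layer")
    total = 0.0
    for la, lb, w in zip(fa, fb, weights):
        da, db = la.data, lb.data
        na = da / np.sqrt((da ** 2).sum(axis=1, keepdims=True) + 1e-10)
        nb = db / np.sqrt((db ** 2).sum(axis=1, keepdims=True) + 1e-10)
        d2 = (na - nb) ** 2
        wv = np.asarray(w, np.float64).reshape(1, -1, 1, 1)
        total += float((d2 * wv).sum(axis=1).mean())
    return total


# ------------------------------------------------------------------ reports

@dataclass
class MetricReport:
    fid: float
    lpips: float
    psnr: float
    ssim: float
    mse: float
    cs: float
    ed: float
    dl_features: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("fid", "lpips", "psnr", "ssim", "mse", "cs", "ed", "dl_features")}


def _as_raw8_array(img) -> np.ndarray:
    if isinstance(img, Image):
        if img.range != RAW8:
            from .stain_io import denormalize
            img = denormalize(img)
        return img.data
    return np.asarray(img, np.float32)


def _to_norm_nchw(img) -> np.ndarray:
    arr = _as_raw8_array(img)
    return (arr / 127.5 - 1.0).transpose(2, 0, 1)[None].astype(np.float32)


def _matched_files(real_dir, fake_dir):
    exts = (".png", ".tif", ".tiff", ".jpg", ".jpeg")
    real = {p.name: p for p in sorted(Path(real_dir).iterdir()) if p.suffix.lower() in exts}
    fake = {p.name: p for p in sorted(Path(fake_dir).iterdir()) if p.suffix.lower() in exts}
    orphans = sorted(set(real) ^ set(fake))
    if orphans:
        raise ValueError(f"unmatched filenames between directories: {orphans[:10]}")
    if not real:
        raise ValueError("no images found to compare")
    return [(real[k], fake[k]) for k in sorted(real)]


def report(real_dir, fake_dir, extractor=None, lpips_weights=None,
           deep_feature_fn=None, ssim_params: SsimParams = SsimParams()) -> MetricReport:
    """Full Table-style metric row over filename-matched directories.

    Per-pair PSNR/SSIM/MSE/CS/ED/LPIPS are averaged over pairs; FID is
    computed from pooled deep-feature statistics of the two sets.
    ``dl_features`` is the mean cosine similarity of deep features of
    matched pairs (``deep_feature_fn`` maps a raw8 array to a vector; the
    pooled extractor features are used when it is omitted — a documented
    interpretation, the metric having no canonical definition).
    """
    from .features import default_extractor, default_lpips_weights
    if extractor is None:
        extractor = default_extractor()
    if lpips_weights is None:
        lpips_weights = default_lpips_weights(extractor)
    if deep_feature_fn is None:
        deep_feature_fn = lambda arr: extractor.pooled(Tensor(_to_norm_nchw(arr)))[0]

    pairs = _matched_files(real_dir, fake_dir)
    acc = {k: [] for k in ("psnr", "ssim", "mse", "cs", "ed", "lpips", "dl")}
    feats_real, feats_fake = [], []
    for rp, fp in pairs:
        ra, fa = read_image(rp).data, read_image(fp).data
        pv, mv = psnr(ra, fa)
        acc["psnr"].append(pv)
        acc["mse"].append(mv)
        acc["ssim"].append(ssim(ra, fa, ssim_params))
        acc["cs"].append(cosine_similarity(ra.ravel(), fa.ravel()))
        acc["ed"].append(euclidean_distance(ra.ravel(), fa.ravel()))
        acc["lpips"].append(lpips(ra, fa, extractor, lpips_weights))
        acc["dl"].append(cosine_similarity(deep_feature_fn(ra), deep_feature_fn(fa)))
        feats_real.append(extractor.pooled(Tensor(_to_norm_nchw(ra)))[0])
        feats_fake.append(extractor.pooled(Tensor(_to_norm_nchw(fa)))[0])
    if len(pairs) >= 2:
        fid_value = fid(gaussian_stats(np.stack(feats_real)), gaussian_stats(np.stack(feats_fake)))
    else:
        fid_value = float("nan")
    mean = lambda v: float(np.mean(v))
    return MetricReport(
        fid=fid_value, lpips=mean(acc["lpips"]), psnr=mean(acc["psnr"]),
        ssim=mean(acc["ssim"]), mse=mean(acc["mse"]), cs=mean(acc["cs"]),
        ed=mean(acc["ed"]), dl_features=mean(acc["dl"]),
    )


def save_report(rep: MetricReport, out_prefix) -> None:
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    d = rep.as_dict()
    out_prefix.with_suffix(".json").write_text(json.dumps(d, indent=1))
    with open(out_prefix.with_suffix(".csv"), "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(d.keys())
        wtr.writerow([d[k] for k in d])


# ------------------------------------------------------- pixel distributions

def pixel_distribution(real_dir, fake_dir, eps: float = 1e-12):
    """256-bin per-channel intensity histograms (probability-normalized) and
    their mean symmetric KL divergence."""
    def hists(d):
        files = [p for p in sorted(Path(d).iterdir())
                 if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")]
        if not files:
            raise ValueError(f"no images in {d}")
        h = np.zeros((3, 256), np.float64)
        for p in files:
            arr = np.clip(np.round(read_image(p).data), 0, 255).astype(np.int64)
            for c in range(3):
                h[c] += np.bincount(arr[:, :, c].ravel(), minlength=256)
        return h / h.sum(axis=1, keepdims=True)

    hr, hf = hists(real_dir), hists(fake_dir)
    p = hr + eps
    q = hf + eps
    p /= p.sum(axis=1, keepdims=True)
    q /= q.sum(axis=1, keepdims=True)
    skl = 0.5 * ((p * np.log(p / q)).sum(axis=1) + (q * np.log(q / p)).sum(axis=1))
    return hr, hf, float(skl.mean())


def save_histograms(hr: np.ndarray, hf: np.ndarray, path) -> None:
    with open(path, "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["bin", "real_r", "real_g", "real_b", "fake_r", "fake_g", "fake_b"])
        for i in range(256):
            wtr.writerow([i, *hr[:, i].tolist(), *hf[:, i].tolist()])
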