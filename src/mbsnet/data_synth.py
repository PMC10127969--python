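"""Synthetic lesion-like image/mask generation, augmentation, preprocessing.

Generates the kind of data binary medical segmentation networks are trained
on: one to three smooth closed blobs (a circle whose radius is modulated by a
low-order random Fourier series) form the foreground mask; the image is a
background intensity plus a foreground contrast shift with a Gaussian-blurred
boundary, additive Gaussian sensor noise, and optional multiplicative speckle
for an ultrasound-like texture.  Deterministic per (config, seed).

Datasets are written as 8-bit PNG pairs under
``<root>/<split>/{images,masks}/`` with a JSON manifest recording every seed
and parameter, so a dataset is reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class SynthConfig:
    image_size: int = 128
    n_blobs_range: tuple = (1, 3)
    radius_range: tuple = (0.12, 0.3)      # fraction of image size
    boundary_roughness: float = 0.25       # Fourier perturbation amplitude
    fourier_order: int = 5
    bg_level: float = 0.35
    fg_contrast: float = 0.3               # intensity shift inside the mask
    edge_blur: float = 1.5                 # px, boundary softness
    noise_sigma: float = 0.05              # additive Gaussian std (0-1 scale)
    speckle: bool = False                  # multiplicative ultrasound-like noise
    speckle_strength: float = 0.25
    channel_jitter: float = 0.05           # per-channel tint of the lesion
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("radius_range must lie within (0, 0.5)")
        if min(self.noise_sigma, self.speckle_strength, self.boundary_roughness) < 0:
            raise ValueError("noise parameters must be non-negative")
        if not (1 <= self.n_blobs_range[0] <= self.n_blobs_range[1] <= 3):
            raise ValueError("n_blobs_range must be within 1..3")


@dataclass
class SampleRecord:
    image: np.ndarray                      # (H, W, 3) uint8
    mask: np.ndarray                       # (H, W) uint8 in {0, 255}
    seed: int
    params: dict


@dataclass(frozen=True)
class AugmentationSpec:
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    crop_fraction: tuple = (0.8, 1.0)      # range of retained side fraction
    seed: int = 0

    def __post_init__(self):
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        lo, hi = self.crop_fraction
        if not (0 < lo <= hi <= 1):
            raise ValueError("crop_fraction must lie within (0, 1]")


def _blob_mask(rng: np.random.Generator, size: int, cfg: SynthConfig) -> np.ndarray:
    """Union of Fourier-perturbed discs; retries on degenerate draws."""
    n_blobs = rng.integers(cfg.n_blobs_range[0], cfg.n_blobs_range[1] + 1)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_blobs):
        for attempt in range(10):
            r0 = rng.uniform(*cfg.radius_range) * size
            cy = rng.uniform(0.25, 0.75) * size
            cx = rng.uniform(0.25, 0.75) * size
            coef = rng.normal(0, cfg.boundary_roughness, size=(2, cfg.fourier_order))
            theta = np.arctan2(yy - cy, xx - cx)
            modulation = np.ones_like(theta)
            for k in range(1, cfg.fourier_order + 1):
                modulation += (coef[0, k - 1] * np.cos(k * theta)
                               + coef[1, k - 1] * np.sin(k * theta)) / k
            radius = r0 * np.clip(modulation, 0.3, 2.0)
            dist = np.hypot(yy - cy, xx - cx)
            blob = dist <= radius
            if blob.any():
                mask |= blob
                break
        else:
            raise RuntimeError("failed to draw a non-degenerate blob in 10 tries")
    return mask


def generate_sample(cfg: SynthConfig, seed: int) -> SampleRecord:
    """One deterministic image/mask pair for (cfg, seed)."""
    rng = np.random.default_rng((cfg.seed, seed))
    size = cfg.image_size
    mask = _blob_mask(rng, size, cfg)

    soft = gaussian_filter(mask.astype(np.float32), cfg.edge_blur)
    tint = 1.0 + rng.normal(0, cfg.channel_jitter, size=3)
    img = np.empty((size, size, 3), dtype=np.float32)
    for ch in range(3):
        img[:, :, ch] = cfg.bg_level + cfg.fg_contrast * tint[ch] * soft
    if cfg.speckle:
        img *= 1.0 + cfg.speckle_strength * rng.standard_normal(img.shape).astype(np.float32)
    if cfg.noise_sigma > 0:
        img += rng.normal(0, cfg.noise_sigma, size=img.shape).astype(np.float32)
    img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    mask8 = (mask.astype(np.uint8)) * 255
    return SampleRecord(image=img8, mask=mask8, seed=seed,
                        params=dataclasses.asdict(cfg))


def generate_dataset(cfg: SynthConfig, n: int, out_dir,
                     split=(0.7, 0.1, 0.2), overwrite: bool = False) -> dict:
    """Write ``n`` PNG pairs under train/val/test directories plus a manifest.

    Split sizes are floor-allocated to val and test with the remainder in
    train, so fractions that sum to 1 always account for every sample.
    """
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split fractions must sum to 1")
    out_dir = os.fspath(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"output directory {out_dir!r} is not empty")
    n_val = int(n * split[1])
    n_test = int(n * split[2])
    n_train = n - n_val - n_test
    counts = {"train": n_train, "val": n_val, "test": n_test}
    manifest = {"config": dataclasses.asdict(cfg), "n": n,
                "split": list(split), "samples": {}}
    idx = 0
    stats_acc = []
    for split_name, count in counts.items():
        img_dir = os.path.join(out_dir, split_name, "images")
        mask_dir = os.path.join(out_dir, split_name, "masks")
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(mask_dir, exist_ok=True)
        entries = []
        for _ in range(count):
            rec = generate_sample(cfg, seed=idx)
            name = f"{idx:05d}.png"
            Image.fromarray(rec.image).save(os.path.join(img_dir, name))
            Image.fromarray(rec.mask, mode="L").save(os.path.join(mask_dir, name))
            entries.append({"file": name, "seed": rec.seed})
            stats_acc.append(rec.image.reshape(-1, 3))
            idx += 1
        manifest["samples"][split_name] = entries
    pixels = np.concatenate(stats_acc, axis=0).astype(np.float64) / 255.0
    manifest["normalization"] = {"mean": pixels.mean(axis=0).tolist(),
                                 "std": pixels.std(axis=0).tolist()}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_split(data_root, split: str):
    """Read a split back as lists of uint8 arrays (images, masks, names)."""
    img_dir = os.path.join(os.fspath(data_root), split, "images")
    mask_dir = os.path.join(os.fspath(data_root), split, "masks")
    if not os.path.isdir(img_dir):
        raise FileNotFoundError(f"missing split directory {img_dir!r}")
    names = sorted(os.listdir(img_dir))
    if not names:
        raise ValueError(f"split {split!r} is empty")
    images, masks = [], []
    for name in names:
        images.append(np.asarray(Image.open(os.path.join(img_dir, name)).convert("RGB")))
        masks.append(np.asarray(Image.open(os.path.join(mask_dir, name)).convert("L")))
    return images, masks, names


def augment(image: np.ndarray, mask: np.ndarray, spec: AugmentationSpec,
            seed: int):
    """Paired horizontal/vertical flips and random crop-resize.

    The identical geometric transform is applied to image and mask; the crop
    is resized back to the original size (bilinear for the image, nearest for
    the mask) and the mask re-binarized.
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask sizes differ")
    rng = np.random.default_rng((spec.seed, seed))
    img, msk = image, mask
    if rng.random() < spec.hflip_prob:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < spec.vflip_prob:
        img, msk = img[::-1], msk[::-1]
    frac = rng.uniform(*spec.crop_fraction)
    h, w = msk.shape[:2]
    ch, cw = max(1, round(h * frac)), max(1, round(w * frac))
    if ch > h or cw > w:
        raise ValueError("crop larger than image")
    if (ch, cw) != (h, w):
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        img = img[top:top + ch, left:left + cw]
        msk = msk[top:top + ch, left:left + cw]
        img = np.asarray(Image.fromarray(np.ascontiguousarray(img)).resize(
            (w, h), Image.BILINEAR))
        msk = np.asarray(Image.fromarray(np.ascontiguousarray(msk)).resize(
            (w, h), Image.NEAREST))
    img = np.ascontiguousarray(img)
    msk = np.ascontiguousarray(msk)
    msk = np.where(msk >= 128, 255, 0).astype(np.uint8)
    return img, msk


def preprocess(image: np.ndarray, mask: np.ndarray | None, size: int = 320,
               mean=(0.5, 0.5, 0.5), std=(0.25, 0.25, 0.25)):
    """Resize + normalize to network tensors.

    Returns a (3, size, size) float32 image ((x/255 - mean) / std per channel)
    and, if a mask is given, a (1, size, size) float32 binary mask (nearest
    resize, re-binarized).
    """
    img = Image.fromarray(np.ascontiguousarray(image)).resize(
        (size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    arr = (arr - np.asarray(mean, dtype=np.float32)) / np.asarray(std, dtype=np.float32)
    x = np.ascontiguousarray(arr.transpose(2, 0, 1))
    if mask is None:
        return x, None
    msk = Image.fromarray(np.ascontiguousarray(mask)).resize(
        (size, size), Image.NEAREST)
    m = (np.asarray(msk) >= 128).astype(np.float32)[None, :, :]
    return x, m
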