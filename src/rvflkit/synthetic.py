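"""Desk-scale synthetic fixtures: feature clouds, mass patches, tiny backbone.

Three generators make every stage of the pipeline testable without the real
mammography patch set:

* :func:`gen_features` — two equicorrelated Gaussian clouds standing in for
  deep features.  ``separation`` is the per-feature distance between the
  class means in units of the within-class standard deviation; at
  separation 4 a single feature already misclassifies only
  Φ(−2) ≈ 2.3 % of samples, and 24 such features make the classes
  essentially perfectly separable.
* :func:`gen_patches` — 8-bit grayscale mass patches encoding the
  radiological margin taxonomy as the class signal: benign masses are
  smooth, circumscribed ellipses with a soft blurred border; malignant
  masses are irregular blobs with spicules — line segments radiating
  outward from the mass.
* :func:`tiny_backbone` — a fixed, seeded convolution + pooling stack
  producing 128-wide embeddings; never trained, deterministic at inference.

All generators are pure functions of their config, seed included.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image
from scipy import ndimage

from .errors import ValidationError
from .features import FeatureMatrix
from .rng import substream

__all__ = [
    "FeatureSimConfig",
    "PatchSimConfig",
    "PatchSet",
    "gen_features",
    "gen_patches",
    "write_patches",
    "read_patches",
    "TinyConvBackbone",
    "tiny_backbone",
]


@dataclass(frozen=True)
class FeatureSimConfig:
    """Two-class Gaussian feature cloud.

    separation : per-feature mean offset of the malignant class, in units of
        the within-class standard deviation.
    correlation : equicorrelation of the features in [0, 1).
    """

    n_per_class: int = 1000
    dim: int = 24
    separation: float = 4.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1 or self.dim < 1:
            raise ValidationError("n_per_class and dim must be >= 1")
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        if not (0 <= self.correlation < 1):
            raise ValidationError("correlation must be in [0, 1)")


def gen_features(cfg: FeatureSimConfig) -> FeatureMatrix:
    """Draw a balanced two-class Gaussian feature matrix.

    Benign samples are centered at the origin, malignant at
    ``separation``·𝟙; both classes share the equicorrelated covariance
    (1−ρ)I + ρJ with unit marginal variance.
    """
    rng = substream(cfg.seed, "gen_features")
    d, n = cfg.dim, cfg.n_per_class
    rho = cfg.correlation
    # X = sqrt(1-rho)·Z + sqrt(rho)·g·1 has covariance (1-rho)I + rho J
    def draw(n_rows):
        Z = rng.standard_normal((n_rows, d))
        if rho > 0:
            g = rng.standard_normal((n_rows, 1))
            return np.sqrt(1 - rho) * Z + np.sqrt(rho) * g
        return Z
    benign = draw(n)
    malignant = draw(n) + cfg.separation
    values = np.vstack([benign, malignant])
    labels = ["benign"] * n + ["malignant"] * n
    ids = [f"b{i:05d}" for i in range(n)] + [f"m{i:05d}" for i in range(n)]
    return FeatureMatrix(values=values, sample_ids=ids, labels=labels, level_tag="raw")


@dataclass(frozen=True)
class PatchSimConfig:
    """Mammography-like mass patch simulation."""

    size: int = 64
    n_per_class: int = 100
    spicule_count_range: tuple[int, int] = (6, 12)
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValidationError("size must be >= 32 pixels")
        lo, hi = self.spicule_count_range
        if lo < 1 or hi < lo:
            raise ValidationError("spicule_count_range must be positive and ordered")
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class PatchSet:
    """Generated patches: uint8 images, labels, ids and noise-free masks."""

    images: np.ndarray  # (n, size, size) uint8
    labels: list[str]
    sample_ids: list[str]
    masks: np.ndarray  # (n, size, size) bool, pre-noise shape support


def _benign_mask(size, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = size / 2 + rng.uniform(-2, 2, 2)
    a = rng.uniform(0.18, 0.28) * size
    b = rng.uniform(0.18, 0.28) * size
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _malignant_mask(size, rng, spicule_range) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = size / 2 + rng.uniform(-2, 2, 2)
    r0 = rng.uniform(0.14, 0.20) * size
    # irregular core: radius modulated by random low-order harmonics
    phases = rng.uniform(0, 2 * np.pi, 4)
    amps = rng.uniform(0.05, 0.15, 4)
    ang = np.arctan2(yy - cy, xx - cx)
    r = np.hypot(xx - cx, yy - cy)
    bound = r0 * (1 + sum(a * np.cos((k + 2) * ang + p)
                          for k, (a, p) in enumerate(zip(amps, phases))))
    mask = r <= bound
    # spicules: thin radiating segments drawn pixel-wise
    n_spic = int(rng.integers(spicule_range[0], spicule_range[1] + 1))
    length = r0 * rng.uniform(1.6, 2.2, n_spic)
    angles = rng.uniform(0, 2 * np.pi, n_spic)
    for L, a in zip(length, angles):
        t = np.linspace(0, 1, int(3 * L))
        px = cx + t * L * np.cos(a)
        py = cy + t * L * np.sin(a)
        ok = (px >= 0) & (px < size) & (py >= 0) & (py < size)
        ix, iy = np.round(px[ok]).astype(int), np.round(py[ok]).astype(int)
        mask[iy, ix] = True
        # widen near the core so spicules taper outward
        near = t[ok] < 0.4
        mask[np.clip(iy[near] + 1, 0, size - 1), ix[near]] = True
        mask[iy[near], np.clip(ix[near] + 1, 0, size - 1)] = True
    return mask


def gen_patches(cfg: PatchSimConfig) -> PatchSet:
    """Generate balanced benign/malignant mass patches.

    Benign: filled ellipse with a Gaussian-blurred (soft, circumscribed)
    border.  Malignant: irregular blob plus radiating spicules, lightly
    blurred so lines stay visible.  Additive Gaussian noise with
    ``noise_sd`` grey levels; output is 8-bit grayscale.
    """
    rng = substream(cfg.seed, "gen_patches")
    n, size = cfg.n_per_class, cfg.size
    images = np.empty((2 * n, size, size), dtype=np.uint8)
    masks = np.empty((2 * n, size, size), dtype=bool)
    labels, ids = [], []
    background, foreground = 60.0, 180.0
    for i in range(2 * n):
        malignant = i >= n
        if malignant:
            mask = _malignant_mask(size, rng, cfg.spicule_count_range)
            blur = 0.8
        else:
            mask = _benign_mask(size, rng)
            blur = 2.0
        img = np.where(mask, foreground, background).astype(float)
        img = ndimage.gaussian_filter(img, sigma=blur)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0, cfg.noise_sd, img.shape)
        images[i] = np.clip(img, 0, 255).astype(np.uint8)
        masks[i] = mask
        labels.append("malignant" if malignant else "benign")
        ids.append(f"{'m' if malignant else 'b'}{i % n:05d}")
    return PatchSet(images=images, labels=labels, sample_ids=ids, masks=masks)


def write_patches(patches: PatchSet, out_dir) -> str:
    """Write patches as PNG files plus a manifest CSV (filename, label)."""
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "sample_id", "label"])
        for img, sid, label in zip(patches.images, patches.sample_ids, patches.labels):
            fname = f"{sid}.png"
            Image.fromarray(img, mode="L").save(os.path.join(out_dir, fname))
            writer.writerow([fname, sid, label])
    return manifest


def read_patches(manifest_path) -> PatchSet:
    """Load patches back from a manifest CSV and its PNG files."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    images, labels, ids = [], [], []
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            arr = np.asarray(Image.open(os.path.join(base, row["filename"])))
            images.append(arr)
            ids.append(row["sample_id"])
            labels.append(row["label"])
    images = np.stack(images)
    return PatchSet(
        images=images,
        labels=labels,
        sample_ids=ids,
        masks=np.zeros_like(images, dtype=bool),
    )


class TinyConvBackbone:
    """Fixed random convolutional embedder: 2 conv/pool stages + projection.

    Never trained; weights are frozen draws from the seed's substream, so
    identical seeds give identical embeddings.  Accepts (n, H, W) uint8 or
    float batches and returns (n, 128) embeddings.
    """

    embedding_width = 128

    def __init__(self, seed: int = 0, input_shape=(64, 64, 1)):
        self.seed = seed
        self.input_shape = input_shape
        rng = substream(seed, "tiny_backbone")
        self.k1 = rng.uniform(-1, 1, (3, 3, 1, 8)) / 3.0
        self.k2 = rng.uniform(-1, 1, (3, 3, 8, 16)) / np.sqrt(72)
        h1 = (input_shape[0] - 2) // 4
        h2 = (h1 - 2) // 4
        w1 = (input_shape[1] - 2) // 4
        w2 = (w1 - 2) // 4
        flat = h2 * w2 * 16
        self.proj = rng.uniform(-1, 1, (flat, self.embedding_width)) / np.sqrt(flat)

    @staticmethod
    def _conv(x, kern):
        win = sliding_window_view(x, (3, 3), axis=(1, 2))
        return np.einsum("nhwcij,ijco->nhwo", win, kern)

    @staticmethod
    def _pool(x, p=4):
        n, h, w, c = x.shape
        h2, w2 = (h // p) * p, (w // p) * p
        x = x[:, :h2, :w2]
        return x.reshape(n, h2 // p, p, w2 // p, p, c).mean(axis=(2, 4))

    def forward(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        x = (x / 255.0)[..., None]  # n,H,W,1 in [0,1]
        x = np.maximum(self._conv(x, self.k1), 0.0)
        x = self._pool(x, 4)
        x = np.maximum(self._conv(x, self.k2), 0.0)
        x = self._pool(x, 4)
        n = x.shape[0]
        return x.reshape(n, -1) @ self.proj


def tiny_backbone(seed: int = 0, input_shape=(64, 64, 1)) -> TinyConvBackbone:
    """Seeded desk-scale backbone satisfying the backbone contract."""
    return TinyConvBackbone(seed=seed, input_shape=input_shape)
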