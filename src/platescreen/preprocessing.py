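"""Per-channel normalization and the augmentation operator family.

Normalization follows the screening convention: per-channel mean and
standard deviation are computed on the 0-1 scale from the *training* crops
only, and a raw 0-255 pixel p is standardized as

    p_norm = (p - mu*255) / (sigma*255)

so the training set itself lands at mean 0, sd 1 per channel.

Augmentation applies exactly one randomly chosen operator to a seeded
~10% sample of the dataset.  Copies keep their crop provenance and carry an
``augmented`` flag so they can never leak into validation or test folds.
Solarization has two modes: the classic invert-above-threshold form
(default; bright pixels turn dark) and a literal indicator-product mask
(p * [p > t]); both are first-class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import warp

from .imaging import CropImage

__all__ = [
    "ChannelStats",
    "AugmentationPolicy",
    "compute_channel_stats",
    "normalize",
    "denormalize",
    "solarize",
    "multiplicative_noise",
    "rgb_shift",
    "hflip",
    "vflip",
    "rot90",
    "augment_dataset",
    "AUGMENT_OPS",
]


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean/sd of training pixels on the 0-1 scale."""

    mu: tuple[float, float, float]
    sigma: tuple[float, float, float]
    n_pixels: int

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be > 0 per channel")

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(
            {"mu": list(self.mu), "sigma": list(self.sigma), "n_pixels": self.n_pixels}))

    @classmethod
    def from_json(cls, path: Path) -> "ChannelStats":
        d = json.loads(Path(path).read_text())
        return cls(mu=tuple(d["mu"]), sigma=tuple(d["sigma"]), n_pixels=int(d["n_pixels"]))


def compute_channel_stats(train_crops: Sequence[CropImage]) -> ChannelStats:
    """Pool all training pixels per channel and return mean/sd on [0, 1].

    Raises on an empty collection or a constant channel (sigma would be 0,
    making normalization undefined).
    """
    crops = list(train_crops)
    if not crops:
        raise ValueError("cannot compute channel stats from an empty collection")
    n = 0
    s1 = np.zeros(3)
    s2 = np.zeros(3)
    for c in crops:
        px = np.asarray(c.pixels, dtype=np.float64) / 255.0
        n += px.shape[0] * px.shape[1]
        s1 += px.sum(axis=(0, 1))
        s2 += (px ** 2).sum(axis=(0, 1))
    mu = s1 / n
    var = np.maximum(s2 / n - mu ** 2, 0.0)
    sigma = np.sqrt(var)
    if np.any(sigma <= 0):
        bad = [i for i, s in enumerate(sigma) if s <= 0]
        raise ValueError(f"constant channel(s) {bad}: sigma = 0, normalization undefined")
    return ChannelStats(mu=tuple(mu), sigma=tuple(sigma), n_pixels=n)


def normalize(c: CropImage, s: ChannelStats) -> CropImage:
    """Standardize raw 0-255 pixels: (p - mu*255) / (sigma*255) per channel."""
    mu = np.asarray(s.mu) * 255.0
    sigma = np.asarray(s.sigma) * 255.0
    px = (np.asarray(c.pixels, dtype=np.float64) - mu) / sigma
    return replace(c, pixels=px)


def denormalize(c: CropImage, s: ChannelStats) -> CropImage:
    """Inverse of :func:`normalize` (for inspection; exact up to float error)."""
    mu = np.asarray(s.mu) * 255.0
    sigma = np.asarray(s.sigma) * 255.0
    return replace(c, pixels=np.asarray(c.pixels, dtype=np.float64) * sigma + mu)


# ---------------------------------------------------------------------------
# augmentation operators — all act on [0, 1] float arrays


def solarize(img: np.ndarray, threshold: float = 0.95, mode: str = "invert_above") -> np.ndarray:
    """Solarization: bright pixels invert (default) or are masked to zero.

    ``invert_above``: p > t -> 1 - p.  ``literal_mask``: p -> p * [p > t],
    the raw indicator-product form.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    img = np.asarray(img, dtype=np.float64)
    if mode == "invert_above":
        return np.where(img > threshold, 1.0 - img, img)
    if mode == "literal_mask":
        return img * (img > threshold)
    raise ValueError(f"unknown solarize mode {mode!r}")


def multiplicative_noise(
    img: np.ndarray,
    noise_range: tuple[float, float] = (-0.2, 0.2),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-pixel p -> clip(p * (1 + u)) with u ~ Uniform(lo, hi), seeded."""
    lo, hi = noise_range
    if lo > hi:
        raise ValueError("noise_range lo must be <= hi")
    if lo < -1.0:
        raise ValueError("noise_range lo must be >= -1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.uniform(lo, hi, size=np.asarray(img).shape)
    return np.clip(np.asarray(img, dtype=np.float64) * (1.0 + u), 0.0, 1.0)


def rgb_shift(img: np.ndarray, shifts: tuple[float, float, float]) -> np.ndarray:
    """Add a per-channel constant and clip to [0, 1]."""
    if any(abs(s) > 1.0 for s in shifts):
        raise ValueError("shifts must be within [-1, 1]")
    return np.clip(np.asarray(img, dtype=np.float64) + np.asarray(shifts), 0.0, 1.0)


def hflip(img: np.ndarray) -> np.ndarray:
    return img[:, ::-1].copy()


def vflip(img: np.ndarray) -> np.ndarray:
    return img[::-1].copy()


def rot90(img: np.ndarray, k: int = 1) -> np.ndarray:
    return np.rot90(img, k=k, axes=(0, 1)).copy()


def _gaussian_noise(img, rng, sd=0.03):
    return np.clip(img + rng.normal(0.0, sd, size=img.shape), 0.0, 1.0)


def _gaussian_blur(img, rng, sigma=1.0):
    return ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))


def _motion_blur(img, rng, length=5):
    # 1-D box kernel along a random axis: crude linear camera-motion streak
    axis = int(rng.integers(0, 2))
    size = [1, 1, 1]
    size[axis] = length
    return ndimage.uniform_filter(img, size=tuple(size))


def _sharpen(img, rng, amount=0.5):
    blurred = ndimage.gaussian_filter(img, sigma=(1, 1, 0))
    return np.clip(img + amount * (img - blurred), 0.0, 1.0)


def _emboss(img, rng, strength=0.5):
    kernel = np.array([[-1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]) * strength
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = ndimage.convolve(img[:, :, ch], kernel) + 0.5
    return np.clip(out, 0.0, 1.0)


def _optical_distortion(img, rng, k=0.05):
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rmax = np.hypot(cy, cx)

    def _map(coords):
        y = coords[:, 0] - cy
        x = coords[:, 1] - cx
        r = np.hypot(y, x) / rmax
        f = 1.0 + k * r ** 2
        return np.column_stack([y * f + cy, x * f + cx])

    return warp(img, _map, preserve_range=True)


def _sun_flare(img, rng, intensity=0.25, radius_frac=0.4):
    h, w = img.shape[:2]
    cy = rng.uniform(0, h)
    cx = rng.uniform(0, w)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx) / (radius_frac * max(h, w))
    flare = intensity * np.exp(-r ** 2)
    return np.clip(img + flare[:, :, None], 0.0, 1.0)


def _snow(img, rng, density=0.002, brightness=0.9):
    h, w = img.shape[:2]
    mask = rng.random((h, w)) < density
    out = img.copy()
    out[mask] = np.maximum(out[mask], brightness)
    return out


def _seeded(fn):
    return lambda img, rng: fn(img, rng)


#: The enabled-operator registry; each op maps ([0,1] image, rng) -> image.
AUGMENT_OPS: dict[str, Callable[[np.ndarray, np.random.Generator], np.ndarray]] = {
    "hflip": lambda img, rng: hflip(img),
    "vflip": lambda img, rng: vflip(img),
    "rot90": lambda img, rng: rot90(img, k=int(rng.integers(1, 4))),
    "solarize": lambda img, rng: solarize(img, 0.95),
    "multiplicative_noise": lambda img, rng: multiplicative_noise(img, (-0.2, 0.2), rng),
    "rgb_shift": lambda img, rng: rgb_shift(img, tuple(rng.uniform(-0.1, 0.1, size=3))),
    "motion_blur": _seeded(_motion_blur),
    "optical_distortion": _seeded(_optical_distortion),
    "gaussian_noise": _seeded(_gaussian_noise),
    "gaussian_blur": _seeded(_gaussian_blur),
    "sun_flare": _seeded(_sun_flare),
    "snow": _seeded(_snow),
    "sharpen": _seeded(_sharpen),
    "emboss": _seeded(_emboss),
}


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which operators may be applied, to what fraction, under which seed."""

    fraction: float = 0.10
    ops: tuple[str, ...] = tuple(AUGMENT_OPS)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        unknown = set(self.ops) - set(AUGMENT_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
        if self.fraction > 0 and not self.ops:
            raise ValueError("fraction > 0 requires a non-empty op set")


def apply_op(name: str, img01: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply one named operator to a [0, 1] float image."""
    return AUGMENT_OPS[name](np.asarray(img01, dtype=np.float64), rng)


def select_augmentation(
    n: int, policy: AugmentationPolicy
) -> list[tuple[int, str]]:
    """Seeded plan: which crop indices get which single operator.

    round(fraction * n) indices drawn without replacement, each paired with
    one uniformly chosen enabled op.
    """
    k = int(round(policy.fraction * n))
    if k == 0:
        return []
    rng = np.random.default_rng(policy.rng_seed)
    idx = rng.choice(n, size=k, replace=False)
    ops = rng.choice(list(policy.ops), size=k)
    return [(int(i), str(o)) for i, o in zip(idx, ops)]


def augment_dataset(
    crops: Sequence[CropImage], policy: AugmentationPolicy
) -> list[CropImage]:
    """Originals plus round(fraction*N) augmented copies, flagged and seeded.

    Each selected crop receives exactly one operator; copies carry
    ``augmented=True`` so downstream splits exclude them from validation
    and test folds.
    """
    crops = list(crops)
    plan = select_augmentation(len(crops), policy)
    out = list(crops)
    rng = np.random.default_rng(np.random.SeedSequence([policy.rng_seed, 1]))
    for i, op in plan:
        src = crops[i]
        img01 = np.asarray(src.pixels, dtype=np.float64) / 255.0
        aug = apply_op(op, img01, rng)
        px = np.clip(np.rint(aug * 255.0), 0, 255).astype(np.uint8)
        out.append(replace(src, pixels=px, augmented=True))
    return out
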