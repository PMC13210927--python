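"""Preprocessing, leakage-free dataset splitting and training-set augmentation.

The preparation pipeline mirrors common practice for field imagery:

1. resize to a fixed spatial size with bilinear interpolation;
2. rescale intensities from [0, 255] to [0, 1];
3. standardise each channel with the ImageNet mean and standard deviation.

Splitting happens *before* augmentation: the raw samples are shuffled once
(seeded) and partitioned 8:1:1 by default, then only the training split is
expanded by stochastic transforms until it reaches ``N * train_ratio``
samples.  Validation and test sets therefore contain only original images —
no augmented view of a held-out image can leak into training.

Geometric transforms (flips, rotation) are applied identically to image and
mask (nearest-neighbour resampling for the mask); photometric transforms
(brightness/contrast, blur, Gaussian noise) touch the image only.  Images are
float arrays in [0, 1] throughout augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .nn import bilinear_resize_array

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

# Hybrid-dataset composition: 553 maize images out of 834 originals
# (281 from the public benchmark component).
MAIZE_IMAGES = 553
HYBRID_TOTAL_IMAGES = 834

# 3x3 Gaussian blur kernel (binomial approximation)
_BLUR_KERNEL = np.outer([1.0, 2.0, 1.0], [1.0, 2.0, 1.0]) / 16.0


def composition_percentage(part: int, total: int) -> float:
    """Share of a category in a dataset, as a percentage."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * part / total


@dataclass(frozen=True)
class NormalizationSpec:
    """Resize + intensity standardisation parameters."""

    resize_to: tuple[int, int] = (512, 512)
    channel_mean: tuple[float, float, float] = IMAGENET_MEAN
    channel_std: tuple[float, float, float] = IMAGENET_STD

    def __post_init__(self):
        if any(s <= 0 for s in self.channel_std):
            raise ValueError("channel_std components must be strictly positive")
        if any(d <= 0 for d in self.resize_to):
            raise ValueError("resize_to dimensions must be positive")


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation parameters.

    ``target_total`` is the size the *whole* dataset is nominally expanded to;
    the training split is grown until it holds ``target_total * split_ratios[0]``
    samples.  ``noise_variance`` is on the [0, 1] intensity scale.
    """

    target_total: int = 5000
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    brightness_contrast_alpha: tuple[float, float] = (0.8, 1.2)
    flip_probability: float = 0.5
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    blur_kernel: int = 3
    noise_variance: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.target_total <= 0:
            raise ValueError("target_total must be positive")
        if any(r <= 0 for r in self.split_ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if self.blur_kernel % 2 != 1:
            raise ValueError("blur_kernel must be odd")


@dataclass
class Sample:
    """An image/mask pair; ``source`` is the raw-training index an augmented
    copy derives from (None for originals)."""

    image: np.ndarray
    mask: np.ndarray
    source: int | None = None


def preprocess(image: np.ndarray, spec: NormalizationSpec = NormalizationSpec()
               ) -> np.ndarray:
    """Resize, rescale [0,255] -> [0,1] and standardise; returns C x H x W."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[:2] != tuple(spec.resize_to):
        img = bilinear_resize_array(img, tuple(spec.resize_to))
    img = img / 255.0
    mean = np.asarray(spec.channel_mean, dtype=np.float32)
    std = np.asarray(spec.channel_std, dtype=np.float32)
    out = (img - mean) / std
    return np.ascontiguousarray(out.transpose(2, 0, 1))


def split_dataset(samples: Sequence, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded shuffle + disjoint partition; floor sizes for val/test,
    remainder assigned to train."""
    if len(samples) == 0:
        raise ValueError("cannot split an empty sample list")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n = len(samples)
    order = np.random.default_rng(seed).permutation(n)
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_val - n_test
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


# -- individual transforms ---------------------------------------------------

def _rotate_pair(image, mask, theta):
    img = ndimage.rotate(image, theta, axes=(1, 0), reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask.astype(np.float32), theta, axes=(1, 0),
                         reshape=False, order=0, mode="constant", cval=0.0)
    return img, (msk > 0.5).astype(mask.dtype)


def _brightness_contrast(image, rng, alpha_range):
    alpha = rng.uniform(*alpha_range)
    beta = rng.uniform(-0.1, 0.1)
    return np.clip(alpha * image + beta, 0.0, 1.0)


def _blur(image, k):
    kernel = _BLUR_KERNEL if k == 3 else _gauss_kernel(k)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[:, :, c] = ndimage.convolve(image[:, :, c], kernel, mode="reflect")
    return out


def _gauss_kernel(k: int) -> np.ndarray:
    sigma = 0.3 * ((k - 1) * 0.5 - 1) + 0.8
    ax = np.arange(k) - (k - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    kern = np.outer(g, g)
    return kern / kern.sum()


def _noise(image, rng, variance):
    noisy = image + rng.normal(0.0, np.sqrt(variance), size=image.shape)
    return np.clip(noisy, 0.0, 1.0).astype(np.float32)


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 config: AugmentConfig = AugmentConfig(),
                 rng: np.random.Generator | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one or more stochastic transforms to an image/mask pair.

    Each transform fires through an independent Bernoulli gate (flips at
    ``flip_probability``, the rest at 0.5); draws are repeated until at least
    one transform fires, so the output is never a verbatim copy by
    construction of the gates.  The returned mask stays binary.
    """
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask)
    if img.shape[:2] != msk.shape[:2]:
        raise ValueError(f"image/mask spatial dims differ: "
                         f"{img.shape[:2]} vs {msk.shape[:2]}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    while True:
        gates = {
            "hflip": rng.uniform() < config.flip_probability,
            "vflip": rng.uniform() < config.flip_probability,
            "rotate": rng.uniform() < 0.5,
            "bc": rng.uniform() < 0.5,
            "blur": rng.uniform() < 0.5,
            "noise": rng.uniform() < 0.5,
        }
        theta = rng.uniform(*config.rotation_range)
        if any(gates.values()):
            break

    if gates["hflip"]:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if gates["vflip"]:
        img, msk = img[::-1].copy(), msk[::-1].copy()
    if gates["rotate"]:
        img, msk = _rotate_pair(img, msk, theta)
    if gates["bc"]:
        img = _brightness_contrast(img, rng, config.brightness_contrast_alpha)
    if gates["blur"]:
        img = _blur(img, config.blur_kernel)
    if gates["noise"]:
        img = _noise(img, rng, config.noise_variance)
    return img.astype(np.float32), msk


def build_augmented_training_set(train_raw: Sequence[tuple[np.ndarray, np.ndarray]],
                                 config: AugmentConfig = AugmentConfig()
                                 ) -> list[Sample]:
    """Grow the training split to ``target_total * train_ratio`` samples.

    Only ``train_raw`` is ever read; each augmented sample records the raw
    index it was derived from.  If the bound is already satisfied the input
    is returned unchanged (as originals).
    """
    if len(train_raw) == 0:
        raise ValueError("train_raw must be non-empty")
    target = int(np.floor(config.target_total * config.split_ratios[0]))
    out = [Sample(image=np.asarray(img), mask=np.asarray(msk), source=None)
           for img, msk in train_raw]
    rng = np.random.default_rng(config.seed)
    while len(out) < target:
        src = int(rng.integers(0, len(train_raw)))
        img, msk = train_raw[src]
        aug_img, aug_msk = augment_pair(img, msk, config, rng)
        out.append(Sample(image=aug_img, mask=aug_msk, source=src))
    return out
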