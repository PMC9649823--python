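"""Random training-time augmentation: crop, flip, rotation, intensity shift.

Each transform fires independently with probability ``p`` (default 0.1).
Spatial transforms are applied identically to image and labels (labels with
nearest-neighbour interpolation); the intensity shift touches only the
image. Rotations are about the axial axis: either a 90-degree multiple
(when the in-plane shape is square) or a small-angle (+-10 degree)
resampled rotation. The intensity shift is uniform within +-0.1 on the
normalized [0, 1] scale. All randomness comes from the caller's generator,
so a fixed seed reproduces the augmentation stream exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "augment"]


@dataclass(frozen=True)
class AugmentConfig:
    p: float = 0.1
    transforms: tuple[str, ...] = ("crop", "flip", "rotation", "intensity")
    crop_shape: tuple[int, int, int] | None = None
    flip_axis: int | None = None  # None: drawn uniformly from (0, 1, 2)
    small_angle_deg: float = 10.0
    intensity_shift: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        unknown = set(self.transforms) - {"crop", "flip", "rotation", "intensity"}
        if unknown:
            raise ValueError(f"unknown transforms {sorted(unknown)}")


def _random_crop(image, labels, shape, rng):
    shape = tuple(min(s, d) for s, d in zip(shape, image.shape))
    starts = [rng.integers(0, d - s + 1) for d, s in zip(image.shape, shape)]
    sl = tuple(slice(a, a + s) for a, s in zip(starts, shape))
    return image[sl], labels[sl]


def _rotate(image, labels, cfg, rng):
    square = image.shape[1] == image.shape[2]
    if square and rng.random() < 0.5:
        k = int(rng.integers(1, 4))
        return np.rot90(image, k, axes=(1, 2)), np.rot90(labels, k, axes=(1, 2))
    angle = float(rng.uniform(-cfg.small_angle_deg, cfg.small_angle_deg))
    img = ndimage.rotate(image, angle, axes=(2, 1), reshape=False, order=1, mode="nearest")
    lab = ndimage.rotate(labels, angle, axes=(2, 1), reshape=False, order=0, mode="nearest")
    return img, lab


def augment(image: np.ndarray, labels: np.ndarray, cfg: AugmentConfig | None = None,
            rng: np.random.Generator | None = None, seed: int | None = None):
    """Apply the configured random transforms; returns (image, labels) copies."""
    cfg = cfg or AugmentConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    if image.shape != labels.shape:
        raise ValueError("image and labels must share a shape")
    image = np.ascontiguousarray(image)
    labels = np.ascontiguousarray(labels)

    if "crop" in cfg.transforms and rng.random() < cfg.p:
        shape = cfg.crop_shape or tuple(max(1, int(0.9 * d)) for d in image.shape)
        image, labels = _random_crop(image, labels, shape, rng)
    if "flip" in cfg.transforms and rng.random() < cfg.p:
        axis = cfg.flip_axis if cfg.flip_axis is not None else int(rng.integers(0, 3))
        image, labels = np.flip(image, axis), np.flip(labels, axis)
    if "rotation" in cfg.transforms and rng.random() < cfg.p:
        image, labels = _rotate(image, labels, cfg, rng)
    if "intensity" in cfg.transforms and rng.random() < cfg.p:
        image = image + float(rng.uniform(-cfg.intensity_shift, cfg.intensity_shift))
    return np.ascontiguousarray(image), np.ascontiguousarray(labels)
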