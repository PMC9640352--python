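"""Seeded on-the-fly augmentations for paired (volume, mask) training data.

Seven transforms — intensity scaling, contrast (gamma) adjustment, Gaussian
smoothing, Gaussian sharpening (unsharp masking), flipping, in-plane
rotation, and elastic 3D deformation — are each applied independently with a
configurable probability (default 0.3).  Spatial transforms are applied
identically to the image and the mask, with nearest-neighbor interpolation
for the mask so it stays exactly binary; intensity transforms never touch
the mask.  A single shared RNG stream drives every draw so one seed
reproduces the whole augmentation bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import UsageError
from .volume_io import BinaryMask, Volume, check_same_shape

__all__ = ["AugmentConfig", "apply_augmentations", "ALL_TRANSFORMS"]

#: Application order is fixed so a seed reproduces the full pipeline.
ALL_TRANSFORMS = (
    "intensity_scale", "contrast", "smooth", "sharpen", "flip", "rotation", "elastic",
)


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform ranges; lo <= hi everywhere, probability in [0, 1].

    The rotation range (+-0.4 rad) and application probability (0.3) mirror
    common abdominal-MR training settings; the remaining ranges are
    conservative, visually plausible defaults since the study protocol draws
    them "randomly" without stating bounds.  Rotation is about the axial
    axis (in the sagittal-coronal plane), which preserves anatomy.
    """

    probability: float = 0.3
    rotation_range: tuple[float, float] = (-0.4, 0.4)  # radians
    flip_axes: tuple[int, ...] = (0, 1, 2)
    intensity_scale_range: tuple[float, float] = (0.9, 1.1)
    contrast_gamma_range: tuple[float, float] = (0.7, 1.4)
    gaussian_smooth_sigma_range: tuple[float, float] = (0.25, 1.0)
    gaussian_sharpen_range: tuple[float, float] = (0.1, 0.5)
    elastic_magnitude: tuple[float, float] = (1.0, 4.0)  # voxels
    elastic_grid_spacing: float = 8.0
    transforms: tuple[str, ...] = ALL_TRANSFORMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise UsageError("probability must be in [0, 1]")
        for name in (
            "rotation_range", "intensity_scale_range", "contrast_gamma_range",
            "gaussian_smooth_sigma_range", "gaussian_sharpen_range", "elastic_magnitude",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise UsageError(f"{name} must be ordered (lo <= hi), got ({lo}, {hi})")
        if not self.flip_axes or not set(self.flip_axes) <= {0, 1, 2}:
            raise UsageError("flip_axes must be a non-empty subset of {0, 1, 2}")
        if self.elastic_grid_spacing <= 0:
            raise UsageError("elastic_grid_spacing must be > 0")
        if not set(self.transforms) <= set(ALL_TRANSFORMS):
            raise UsageError(f"unknown transforms: {set(self.transforms) - set(ALL_TRANSFORMS)}")


def _gamma_adjust(data: np.ndarray, gamma: float) -> np.ndarray:
    lo, hi = data.min(), data.max()
    if hi == lo:
        return data.copy()
    unit = (data - lo) / (hi - lo)
    return unit**gamma * (hi - lo) + lo


def _elastic_fields(shape, rng, magnitude, grid_spacing):
    coarse = [max(2, int(round(s / grid_spacing))) for s in shape]
    fields = []
    for _ in range(3):
        f = rng.standard_normal(coarse)
        f = ndimage.zoom(f, [s / c for s, c in zip(shape, coarse)], order=1)
        f = f[: shape[0], : shape[1], : shape[2]]
        pad = [(0, shape[i] - f.shape[i]) for i in range(3)]
        f = np.pad(f, pad, mode="edge")
        peak = np.abs(f).max()
        fields.append(f / peak * magnitude if peak > 0 else f)
    return fields


def apply_augmentations(
    v: Volume, m: BinaryMask, cfg: AugmentConfig, rng: np.random.Generator | None = None
) -> tuple[Volume, BinaryMask]:
    """Apply each configured transform with probability ``cfg.probability``.

    Returns new (Volume, BinaryMask); inputs are never mutated.  Passing an
    explicit ``rng`` lets callers thread one stream through many samples;
    otherwise a fresh generator is built from ``cfg.seed``.
    """
    check_same_shape(v.data, m.data)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    img = v.data.copy()
    mask = m.data.copy()

    def active(name: str) -> bool:
        return name in cfg.transforms and rng.uniform() < cfg.probability

    # intensity-only transforms (mask untouched)
    if active("intensity_scale"):
        img = img * rng.uniform(*cfg.intensity_scale_range)
    if active("contrast"):
        img = _gamma_adjust(img, rng.uniform(*cfg.contrast_gamma_range))
    if active("smooth"):
        img = ndimage.gaussian_filter(img, rng.uniform(*cfg.gaussian_smooth_sigma_range))
    if active("sharpen"):
        amount = rng.uniform(*cfg.gaussian_sharpen_range)
        img = img + amount * (img - ndimage.gaussian_filter(img, 1.0))

    # spatial transforms (image and mask together)
    if active("flip"):
        axis = int(rng.choice(cfg.flip_axes))
        img = np.flip(img, axis=axis).copy()
        mask = np.flip(mask, axis=axis).copy()
    if active("rotation"):
        angle = np.degrees(rng.uniform(*cfg.rotation_range))
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1, mode="nearest")
        mask = ndimage.rotate(
            mask.astype(np.float64), angle, axes=(0, 1), reshape=False, order=0, mode="nearest"
        )
        mask = (mask > 0.5).astype(np.uint8)
    if active("elastic"):
        magnitude = rng.uniform(*cfg.elastic_magnitude)
        dz = _elastic_fields(img.shape, rng, magnitude, cfg.elastic_grid_spacing)
        base = np.meshgrid(*[np.arange(s) for s in img.shape], indexing="ij")
        coords = [b + d for b, d in zip(base, dz)]
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="nearest")
        mask = (mask > 0.5).astype(np.uint8)

    return Volume(img, v.spacing), BinaryMask(mask, m.spacing)
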