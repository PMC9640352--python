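"""NIfTI volume and binary-mask I/O, resampling and intensity normalization.

This module fixes the coordinate contract every other module relies on:
volumes are 3D arrays with axis 0 = sagittal index, axis 1 = coronal index,
axis 2 = axial slice index, so ``data[:, :, k]`` is one axial slice.  Files
are reoriented to the canonical (closest-to-RAS) orientation on load so that
"axial plane" is well defined regardless of how the scanner stored the data.
Voxel spacing is carried in mm per axis.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, InputError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "resample_to_shape",
    "minmax_normalize",
]


def _validate_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
        raise UsageError(f"spacing must be three positive finite mm values, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    Axial slices are ``data[:, :, k]``; intensities are arbitrary reals but
    must be finite.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume contains NaN or Inf voxels")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} voxel mask aligned to a :class:`Volume` of the same shape."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got {arr.ndim}D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask voxels must be exactly 0 or 1, found values {vals[:5]}")
        self.data = arr.astype(np.uint8)
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


def check_same_shape(a, b) -> None:
    """Raise UsageError when two grids/volumes/masks disagree in shape."""
    sa = a.shape if not isinstance(a, np.ndarray) else a.shape
    sb = b.shape if not isinstance(b, np.ndarray) else b.shape
    if tuple(sa) != tuple(sb):
        raise UsageError(f"shape mismatch: {tuple(sa)} vs {tuple(sb)}")


def _load_canonical(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises a zoo of exceptions
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing


def read_volume(path: str) -> Volume:
    """Read a 3D NIfTI image; spacing comes from the header, intensities are native."""
    data, spacing = _load_canonical(path)
    return Volume(data, spacing)


def read_mask(path: str) -> BinaryMask:
    """Read a NIfTI file as a binary mask: voxels > 0.5 become 1, else 0."""
    data, spacing = _load_canonical(path)
    return BinaryMask((data > 0.5).astype(np.uint8), spacing)


def write_volume(v: Volume | BinaryMask, path: str) -> None:
    """Write a volume or mask as NIfTI-1; masks are stored as uint8 for exact round trips."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise InputError(f"parent directory does not exist: {parent}")
    if isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float64)
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.spacing)
    try:
        nib.save(img, path)
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def resample_to_shape(v: Volume | BinaryMask, target_shape, mode: str = "linear"):
    """Resample to ``target_shape``, rescaling spacing so physical extent is kept.

    Intensity volumes use trilinear interpolation (``mode="linear"``); masks
    must use ``mode="nearest"`` so the output stays binary.
    """
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 2 for s in target_shape):
        raise UsageError(f"target_shape must be three ints >= 2, got {target_shape}")
    if mode not in ("linear", "nearest"):
        raise UsageError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if isinstance(v, BinaryMask) and mode != "nearest":
        raise UsageError("masks must be resampled with mode='nearest'")

    old_shape = v.shape
    new_spacing = tuple(
        v.spacing[i] * old_shape[i] / target_shape[i] for i in range(3)
    )
    if target_shape == tuple(old_shape):
        out = v.data.copy()
    else:
        factors = [target_shape[i] / old_shape[i] for i in range(3)]
        order = 1 if mode == "linear" else 0
        out = ndimage.zoom(
            v.data.astype(np.float64), factors, order=order,
            mode="nearest", grid_mode=True,
        )
        # zoom may be off by one voxel on some ratios; enforce the contract
        out = out[: target_shape[0], : target_shape[1], : target_shape[2]]
        if out.shape != target_shape:
            pad = [(0, target_shape[i] - out.shape[i]) for i in range(3)]
            out = np.pad(out, pad, mode="edge")
    if isinstance(v, BinaryMask):
        return BinaryMask((out > 0.5).astype(np.uint8), new_spacing)
    return Volume(out, new_spacing)


def minmax_normalize(v: Volume) -> Volume:
    """Affinely rescale intensities to span [0, 1].

    A constant volume has no dynamic range; the documented degenerate result
    is all zeros (with a warning).
    """
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi == lo:
        logger.warning("minmax_normalize: constant volume, returning all zeros")
        return Volume(np.zeros_like(v.data), v.spacing)
    return Volume((v.data - lo) / (hi - lo), v.spacing)
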