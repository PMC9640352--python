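"""Seeded synthetic liver phantoms with ground truth and flawed predictions.

The generator emulates the structure of a contrast-enhanced T1-weighted
abdominal volume at test scale: a hyper-intense liver-like organ (a smoothly
deformed superellipsoid), hypo-intense internal lesions, an adjacent
confounder organ whose intensity sits within ``edge_weakness`` of the liver
(manufacturing the weak-edge boundary where level-set leakage happens in
practice), and additive Gaussian noise.  ``perturb_mask`` then produces the
systematically flawed "predicted" masks seen in automated liver
segmentation: uniform boundary under-segmentation, localized leakage into
the neighboring organ, missed lesions, and interior holes.

Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import UsageError
from .volume_io import BinaryMask, Volume, write_volume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "resolve_spec",
    "generate_phantom",
    "perturb_mask",
    "make_suite",
    "PERTURB_MODES",
]

PERTURB_MODES = ("erode_boundary", "dilate_leak", "drop_lesion", "punch_holes")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic phantom.

    Intensities are in [0, 1] with the liver bright over a dark background
    (contrast-enhanced T1 analogy).  ``edge_weakness`` bounds the contrast
    gap between liver and the touching confounder organ.  ``lesions`` may be
    left None to have ``n_lesions`` spheres placed inside the liver by the
    seeded RNG (see :func:`resolve_spec`).
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    liver_center: tuple[float, float, float] | None = None
    #: None scales with the grid: (0.30, 0.25, 0.31) of the shape,
    #: i.e. (19.2, 16.0, 9.9) voxels on the default 64x64x32 grid
    liver_radii: tuple[float, float, float] | None = None
    liver_exponent: float = 2.5
    deform_amplitude: float = 0.12
    deform_sigma: float = 8.0
    n_lesions: int = 2
    lesion_radius: float = 3.0
    lesion_intensity_drop: float = 0.30
    lesions: tuple[tuple[tuple[int, int, int], float, float], ...] | None = None
    confounder_radii: tuple[float, float, float] | None = None  # None: scales with grid
    background_intensity: float = 0.15
    liver_intensity: float = 0.80
    confounder_intensity: float = 0.72
    edge_weakness: float = 0.10
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape):
            raise UsageError("phantom shape must be at least 16 voxels per axis")
        if not (0 <= self.noise_sd < 0.5):
            raise UsageError("noise_sd must be in [0, 0.5)")
        gap = abs(self.liver_intensity - self.confounder_intensity)
        if gap > self.edge_weakness + 1e-12:
            raise UsageError(
                f"liver/confounder contrast {gap:.3f} exceeds edge_weakness {self.edge_weakness}"
            )


@dataclass
class PhantomCase:
    """One suite entry: image, ground truth, flawed initial mask."""

    volume: Volume
    gt: BinaryMask
    init: BinaryMask
    mode: str
    case_id: str
    lesions: tuple = ()


def _superellipsoid(shape, center, radii, exponent):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    f = sum(
        np.abs((grids[i] - center[i]) / radii[i]) ** exponent for i in range(3)
    )
    return f


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def resolve_spec(spec: PhantomSpec) -> PhantomSpec:
    """Concretize seed-dependent fields (lesion placement) into the spec.

    Returned spec has ``lesions`` filled with (center, radius, drop) tuples
    placed strictly inside the liver, so perturbation modes that need lesion
    sites can be driven from it deterministically.
    """
    if spec.lesions is not None:
        return spec
    liver = _liver_mask(spec)
    rng = np.random.default_rng(spec.seed)
    margin = int(np.ceil(spec.lesion_radius)) + 1
    interior = ndimage.binary_erosion(liver, iterations=margin, border_value=0)
    coords = np.argwhere(interior)
    lesions = []
    if len(coords) and spec.n_lesions > 0:
        idx = rng.choice(len(coords), size=min(spec.n_lesions, len(coords)), replace=False)
        for i in np.atleast_1d(idx):
            c = tuple(int(x) for x in coords[i])
            lesions.append((c, float(spec.lesion_radius), float(spec.lesion_intensity_drop)))
    return replace(spec, lesions=tuple(lesions))


def _radii(spec: PhantomSpec) -> tuple[float, float, float]:
    if spec.liver_radii is not None:
        return spec.liver_radii
    return (spec.shape[0] * 0.30, spec.shape[1] * 0.25, spec.shape[2] * 0.31)


def _conf_radii(spec: PhantomSpec) -> tuple[float, float, float]:
    if spec.confounder_radii is not None:
        return spec.confounder_radii
    return (spec.shape[0] * 0.156, spec.shape[1] * 0.14, spec.shape[2] * 0.22)


def _liver_mask(spec: PhantomSpec) -> np.ndarray:
    center = spec.liver_center
    if center is None:
        center = (spec.shape[0] * 0.45, spec.shape[1] * 0.5, spec.shape[2] * 0.5)
    f = _superellipsoid(spec.shape, center, _radii(spec), spec.liver_exponent)
    rng = np.random.default_rng(spec.seed)
    bumps = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.deform_sigma)
    peak = np.abs(bumps).max()
    if peak > 0:
        bumps = bumps / peak
    liver = (f <= 1.0 + spec.deform_amplitude * bumps)
    liver = _largest_component(liver)
    liver = ndimage.binary_fill_holes(liver)
    return liver


def _ball(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((grids[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius**2


def _check_margin(liver: np.ndarray, margin: int = 2) -> None:
    idx = np.argwhere(liver)
    if idx.size == 0:
        raise UsageError("phantom spec produced an empty liver mask")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    shape = np.array(liver.shape)
    if (lo < margin).any() or (hi > shape - 1 - margin).any():
        raise UsageError(
            f"liver mask violates the {margin}-voxel grid margin "
            f"(bbox {lo.tolist()}..{hi.tolist()} in {liver.shape})"
        )


def confounder_center(spec: PhantomSpec, liver: np.ndarray) -> tuple[float, float, float]:
    """Center of the adjacent organ: abutting the liver on the +axis-0 side."""
    if spec.liver_center is None:
        cy, cz = spec.shape[1] * 0.5, spec.shape[2] * 0.5
    else:
        cy, cz = spec.liver_center[1], spec.liver_center[2]
    col = liver[:, int(round(cy)), int(round(cz))]
    x_max = int(np.argwhere(col).max()) if col.any() else int(np.argwhere(liver)[:, 0].max())
    return (x_max + _conf_radii(spec)[0] * 0.85, cy, cz)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask]:
    """Render one noisy phantom volume plus its exact liver mask.

    The ground truth is the whole liver including lesions (the parenchyma
    delineation convention); the confounder organ is not part of it.
    """
    spec = resolve_spec(spec)
    liver = _liver_mask(spec)
    _check_margin(liver)

    img = np.full(spec.shape, spec.background_intensity, dtype=np.float64)
    conf = _superellipsoid(
        spec.shape, confounder_center(spec, liver), _conf_radii(spec), 2.0
    ) <= 1.0
    img[conf & ~liver] = spec.confounder_intensity
    img[liver] = spec.liver_intensity
    for center, radius, drop in spec.lesions:
        lesion = _ball(spec.shape, center, radius) & liver
        img[lesion] = spec.liver_intensity - drop

    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from geometry
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, spec.shape)
    img = np.clip(img, 0.0, 1.0)
    return Volume(img, spec.spacing), BinaryMask(liver.astype(np.uint8), spec.spacing)


def perturb_mask(
    gt: BinaryMask,
    mode: str,
    magnitude: int = 2,
    seed: int = 0,
    lesions=None,
    toward: tuple[float, float, float] | None = None,
) -> BinaryMask:
    """Produce a systematically flawed copy of a ground-truth mask.

    erode_boundary   uniform under-segmentation by ``magnitude`` voxels
    dilate_leak      localized over-segmentation: dilation by ``magnitude``
                     restricted to a boundary patch (nearest the ``toward``
                     point when given, else a random boundary voxel)
    drop_lesion      remove ``magnitude`` lesion-site spheres (needs lesions)
    punch_holes      remove ``magnitude`` random interior spheres

    Erosion/drop/punch never add voxels (FP = 0 against GT); dilation never
    removes any (FN = 0).  Deterministic per seed.
    """
    if mode not in PERTURB_MODES:
        raise UsageError(f"unknown perturbation mode {mode!r}")
    if not gt.data.any():
        raise UsageError("perturb_mask requires a non-empty ground truth")
    if magnitude < 0:
        raise UsageError("magnitude must be >= 0")
    g = gt.data.astype(bool)
    if magnitude == 0:
        return BinaryMask(gt.data.copy(), gt.spacing)
    rng = np.random.default_rng(seed)

    if mode == "erode_boundary":
        out = ndimage.binary_erosion(g, iterations=magnitude, border_value=0)
    elif mode == "dilate_leak":
        structure = ndimage.generate_binary_structure(3, 1)
        boundary = g & ~ndimage.binary_erosion(g, structure=structure, border_value=0)
        coords = np.argwhere(boundary)
        if toward is not None:
            d2 = ((coords - np.asarray(toward)) ** 2).sum(axis=1)
            site = coords[int(np.argmin(d2))]
        else:
            site = coords[rng.integers(len(coords))]
        patch = _ball(g.shape, site, 3 * magnitude)
        out = g | (ndimage.binary_dilation(g, iterations=magnitude) & patch)
    elif mode == "drop_lesion":
        if not lesions:
            raise UsageError("drop_lesion requires lesion metadata")
        order = rng.permutation(len(lesions))
        out = g.copy()
        for i in order[: min(magnitude, len(lesions))]:
            center, radius, _ = lesions[i]
            out &= ~_ball(g.shape, center, radius + 1)
    else:  # punch_holes
        interior = ndimage.binary_erosion(g, iterations=3, border_value=0)
        coords = np.argwhere(interior)
        out = g.copy()
        if len(coords) == 0:
            logger.warning("punch_holes: mask has no interior, returning unchanged")
        else:
            idx = rng.choice(len(coords), size=min(magnitude, len(coords)), replace=False)
            for i in np.atleast_1d(idx):
                out &= ~_ball(g.shape, coords[i], 2.0)

    if not out.any():
        logger.warning("perturb_mask(%s, %d): result is empty", mode, magnitude)
    return BinaryMask(out.astype(np.uint8), gt.spacing)


_MODE_MAGNITUDE = {
    "erode_boundary": 2,
    "dilate_leak": 3,
    "drop_lesion": 1,
    "punch_holes": 2,
}


def make_suite(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seeds=None,
    modes=PERTURB_MODES,
    out_dir: str | None = None,
) -> list[PhantomCase]:
    """Generate n phantom cases with varied anatomy and one flaw mode each.

    Each seed re-randomizes the liver deformation and lesion placement; the
    perturbation mode is drawn from ``modes`` by the case RNG.  When
    ``out_dir`` is given the images/masks are written as NIfTI together with
    a ``manifest.csv`` for CLI batch evaluation.
    """
    if seeds is None:
        seeds = list(range(n))
    seeds = list(seeds)
    if n != len(seeds):
        raise UsageError(f"n = {n} but {len(seeds)} seeds given")

    cases = []
    for seed in seeds:
        spec = resolve_spec(replace(base_spec, seed=int(seed), lesions=None))
        vol, gt = generate_phantom(spec)
        rng = np.random.default_rng(int(seed) + 10_000)
        mode = modes[int(rng.integers(len(modes)))]
        liver = gt.data.astype(bool)
        init = perturb_mask(
            gt, mode, magnitude=_MODE_MAGNITUDE[mode], seed=int(seed) + 20_000,
            lesions=spec.lesions,
            toward=confounder_center(spec, liver) if mode == "dilate_leak" else None,
        )
        cases.append(PhantomCase(vol, gt, init, mode, f"phantom_{seed}", spec.lesions))

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for case in cases:
            paths = {
                kind: os.path.join(out_dir, f"{kind}_{case.case_id}.nii.gz")
                for kind in ("image", "gt", "init")
            }
            write_volume(case.volume, paths["image"])
            write_volume(case.gt, paths["gt"])
            write_volume(case.init, paths["init"])
            rows.append({"volume_id": case.case_id, "mode": case.mode, **paths})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return cases
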