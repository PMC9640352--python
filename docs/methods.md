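# Methods

## Scope and model

`segrefine` implements the post-processing and evaluation half of an
automated liver-parenchyma segmentation workflow: given a 3D image volume
and a binary mask predicted by some upstream model, it (i) refines the mask
with distance-regularized level-set evolution (DRLSE) run independently on
each 2D slice of a chosen plane, (ii) scores masks with the clinical metric
suite, and (iii) provides the loss functions and augmentations such an
upstream model would be trained with, as framework-agnostic references.
Network training itself is out of scope.

## DRLSE refinement

Each slice's level-set function is initialized as a binary step
(φ = −c₀ inside the mask, +c₀ outside, c₀ = 2) and updated by explicit
Euler steps of

∂φ/∂t = μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(g∇φ/|∇φ|) + α g δ_ε(φ)

* **Distance regularization** uses the double-well potential
  p(s) = (1/(2π)²)(1 − cos 2πs) for s ≤ 1 and ½(s−1)² beyond, so
  d_p(s) = p′(s)/s → 1 as s → 0. It keeps |∇φ| ≈ 1 near the contour
  without re-initialization.
* **Edge indicator** g = 1/(1 + |∇(G_σ∗I)|²), computed once per slice with
  central differences and held fixed during evolution.
* **Regularized Dirac** δ_ε(x) = (1/2ε)(1 + cos(πx/ε)) on |x| ≤ ε, zero
  outside; it confines all image-driven forces to a band of width 2ε
  around the zero level set.
* **Discretization**: central differences everywhere, Neumann (replicate)
  borders, |∇φ| floored at 1e-10 in the curvature term, foreground = {φ<0}.
  Outer iterations are checkpoint boundaries only (a callback hook); the
  total number of PDE updates is inner × outer. The evolution is exactly
  deterministic.

### Parameters

| parameter | default | meaning |
|---|---|---|
| α | −5 | area force; negative inflates an inside-negative contour |
| λ | 5 | length/edge-attraction force |
| μ | 0.2 | distance-regularization weight; μ·Δt < 0.25 enforced |
| Δt | 1 | explicit Euler step |
| ε | 0.2 | Dirac band half-width (index units) |
| σ | 0.2 | Gaussian width of the edge indicator (voxels) |
| inner × outer | 45 × 25 | PDE updates between / number of checkpoints |
| c₀ | 2 | binary initialization height |
| edge_scale | 255 | intensity scale applied before computing g |

α, λ, ε, σ, Δt and the iteration counts are the operating point found
optimal for liver-mask refinement in the axial plane; μ and c₀ follow the
classical DRLSE recommendation (μ = 0.2/Δt).

**Why `edge_scale` exists.** Volumes are min-max normalized to [0,1] before
refinement. On that scale the central-difference gradient of any image is
at most 0.5, so g ≥ 0.8 everywhere — the area force |α|·g (≈4–5) then always
exceeds the strongest possible edge attraction λ|∇g| (≲0.5) and the contour
leaks until it fills the slice, regardless of the image. The classical
DRLSE formulation operates on 8-bit intensities, where a strong edge drives
g to ~1e-4 and stops the front dead. `evolve_slice` therefore multiplies
the unit-normalized slice by `edge_scale` (default 255, configurable)
before computing g; `edge_indicator` itself implements the printed formula
unchanged. Measured on the default phantom: without scaling a perfect
initialization degrades to Dice 0.39; with it, an eroded initialization
improves 0.798 → 0.813 and a perfect one stays above 0.998.

2D evolution treats in-plane voxels as isotropic unit squares (index
space); only HD95 uses physical spacing. Slices with an empty initial mask
carry no zero level set and are copied through unchanged. Per-slice images
are taken from the per-volume normalization (not re-normalized per slice),
matching the upstream preprocessing convention.

The parameter sweep evaluates a grid of (α, λ, inner, outer) over a case
list and ranks by mean Dice with first-in-grid-order tie-breaking; points
where any case failed are reported but excluded from ranking.

## Evaluation metrics

Dice, Jaccard, OS = 2FP/(|GT|+|Pred|) and US = 2FN/(|GT|+|Pred|) come from
exact voxel confusion counts; the identities OS+US = 2(1−DSC) and
JAC = DSC/(2−DSC) hold algebraically and are property-tested. When both
masks are empty the pair scores Dice 1, OS = US = 0, and HD95 is undefined
(reported as a missing value) — a documented convention for a degenerate
case. Note US (and OS) ranges up to 2: an empty prediction against a
non-empty GT gives US = 2.

HD95 is the max of the two directed 95th-percentile boundary distances.
Boundary voxels are foreground voxels with at least one face-adjacent
background neighbor (the array border counts as background); distances are
Euclidean in physical mm; percentiles use linear interpolation between
order statistics so results are bit-stable. The printed definition of the
symmetric distance is implemented as max(h₉₅(A,B), h₉₅(B,A)).

Border stripping erodes a mask by an odd-edged voxel cube (3³, 5³, …),
removing the boundary shell where disagreement concentrates so interior
accuracy can be read directly. Whether to score stripped-vs-original or
stripped-vs-stripped is left to the caller (both pairings appear in
practice); the CLI `--strip` option strips both masks.

## Losses

Dice loss uses the squared-denominator form with smoothing ϵ = 1e-6 in
numerator and denominator. The Tversky loss is implemented with soft
counts (TP = Σp·p̂ etc.) so the same code serves binary evaluation and
differentiable-training references; hard counts are the binary special
case, and (α, β) = (0.5, 0.5) reproduces the Dice score exactly. The
generalized Dice loss defaults to the prediction-based first-power weight
w_l = 1/Σ p̂_l; the conventional squared ground-truth weight
(`weight="gt_squared"`) is provided because the first-power form, while
implemented as specified, is unusual — empty-weight classes contribute 0
and are logged. A smoothing ϵ is also added to the Tversky ratio to avoid
0/0 on empty masks.

## Augmentations

Seven transforms (intensity scale, gamma contrast, Gaussian smooth,
unsharp sharpen, flip, axial rotation, elastic 3D deformation), each
applied with probability 0.3 by default from one shared RNG stream, so a
single seed reproduces the pipeline bit-exactly. Rotation is ±0.4 rad about
the axial axis (axial rotation preserves anatomy; other axes are possible
but not default). The numeric ranges for the intensity-family transforms
and the elastic field (scale U(0.9,1.1), γ U(0.7,1.4), smooth σ
U(0.25,1.0), unsharp amount U(0.1,0.5), displacement U(1,4) voxels on an
~8-voxel control grid) are conservative choices made once — the protocol
they mirror states only that values are drawn randomly. Spatial transforms
use nearest-neighbor interpolation for masks, which therefore stay exactly
binary; flips preserve foreground counts exactly, warps within ~10% at
these magnitudes.

## Synthetic phantom

The generator emulates a contrast-enhanced T1-like abdominal volume at
desk scale (default 64×64×32 voxels, 1×1×2 mm): a bright liver-like organ
(intensity 0.80) as a smoothly deformed superellipsoid (low-frequency
Gaussian random modulation of the implicit surface, single 6-connected
component, ≥2-voxel grid margin enforced), hypo-intense spherical lesions
inside it (drop 0.30), a darker background (0.15), an adjacent confounder
organ at intensity 0.72 — within the `edge_weakness` bound (0.10) of the
liver, manufacturing the weak-edge contact where leakage happens — and
additive Gaussian noise (σ = 0.03), clipped to [0,1]. The ground truth is
the liver including lesions (the parenchyma delineation convention).

`perturb_mask` produces the characteristic failure modes of automated
liver segmentation: uniform boundary erosion (under-segmentation), a
localized dilation patch toward the confounder (leakage), removed lesion
sites, and punched interior holes. Erosion/drop/punch never add voxels,
dilation never removes any — so the direction of OS/US effects is known by
construction and tested.

What the phantom does **not** model: MR physics (bias fields, sequence
differences), realistic hepatic shape and vasculature, partial-volume
boundaries, or anisotropic texture. Passing tests therefore demonstrate
algorithmic correctness and the qualitative refinement behavior (recovery
of missed boundary tissue, stability of correct masks, leak direction
control via sign of α), not clinical-grade accuracy on patient data.

## Problem sizes and numerical choices

The default suite is five 64×64×32 phantoms; at the reference operating
point (45×25 = 1125 updates per non-empty slice) one volume refines in
under ten seconds on one CPU, which keeps the full test suite and the
acceptance script in the low minutes. These sizes are the package's test
conditions, chosen so correctness properties are cheap to verify; the
algorithms themselves are size-agnostic and `resample_to_shape` supports
the larger grids used in production (e.g. 256-resampled volumes),
rescaling spacing so physical extent is preserved.

Degenerate inputs are pinned by convention rather than left undefined:
constant volumes min-max normalize to all zeros (with a warning), masks
must be exactly {0,1} (soft files are thresholded at 0.5 on read), and
ties at φ = 0 go to background.

## Known limitations

* Slice-wise 2D evolution cannot use through-plane context; stacked slice
  contours can look terraced in 3D renderings. A volumetric (3D) level set
  is the natural extension and deliberately not implemented here.
* With ε = 0.2 the Dirac band is narrower than one voxel, so the front
  advances in sub-voxel bursts gated by the distance-regularization
  diffusion; progress per iteration is slow, which is why the reference
  operating point uses over a thousand updates per slice.
* The sweep ranks by mean Dice only; a multi-metric ranking (e.g.
  dominated-point filtering on OS/US/HD95) is left to callers via the full
  report table.
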