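# segrefine

Level-set refinement and clinical evaluation of 3D liver-parenchyma
segmentation masks.

Automated liver segmentations from neural networks are good but imperfect:
they under-segment near weak boundaries, leak into neighboring organs
(heart, spleen, stomach, kidney), miss lesions, and leave holes. `segrefine`
post-processes such binary masks with **distance-regularized level-set
evolution (DRLSE)** applied per axial slice, scores them with the standard
clinical metric suite, and ships a seeded synthetic liver-phantom generator
so the entire pipeline is testable without patient data.

## What it computes

**Refinement.** A binary mask initializes a level-set function φ (−c₀
inside, +c₀ outside) on each axial slice, which evolves under

    ∂φ/∂t = μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(g ∇φ/|∇φ|) + α g δ_ε(φ)

with edge indicator g = 1/(1+|∇(G_σ∗I)|²), regularized Dirac δ_ε, and a
double-well distance-regularization potential. A negative area coefficient
α inflates the contour to recover missed tissue; g halts it at image edges.
Defaults: α=−5, λ=5, μ=0.2, Δt=1, ε=0.2, σ=0.2, 45 inner × 25 outer
iterations.

**Evaluation.** From voxel confusion counts (TP/FP/FN/TN):
DSC = 2TP/(2TP+FP+FN), JAC = TP/(TP+FP+FN), OS = 2FP/(|GT|+|Pred|),
US = 2FN/(|GT|+|Pred|) — so OS+US = 2(1−DSC) exactly — plus the symmetric
95th-percentile Hausdorff surface distance (HD95) in mm. Border stripping
(cube erosion) and mask union/intersection support interior-only and
multi-rater analyses.

**Losses.** Reference implementations of Dice loss, generalized Dice loss,
and Tversky loss TI = TP/(TP+αFP+βFN) with the named presets TL46…TL19,
plus the seven seeded training augmentations (flip, rotation, elastic,
intensity/contrast/smooth/sharpen).

## Worked example

```python
from segrefine import DRLSEParams, confusion_counts, dice, evaluate_pair, refine_volume
from segrefine.phantom import PhantomSpec, generate_phantom, perturb_mask

vol, gt = generate_phantom(PhantomSpec(seed=0))          # 64x64x32 phantom
init = perturb_mask(gt, "erode_boundary", 2, seed=0)      # under-segmented "prediction"
refined = refine_volume(vol, init, DRLSEParams())         # slice-wise DRLSE

print(f"init    Dice {dice(confusion_counts(gt, init)):.4f}")
print(f"refined Dice {dice(confusion_counts(gt, refined)):.4f}")
print(evaluate_pair(gt, refined, vol.spacing))
```

prints

```
init    Dice 0.7977
refined Dice 0.8134
MetricReport(dice=0.8133..., jaccard=0.6854..., os=0.00023...,
             us=0.3730..., hd95=4.0, volume_id='')
```

The eroded initialization misses a two-voxel boundary shell everywhere;
the expansion force (α=−5) recovers part of it and stops at the liver edge,
raising Dice while leaving over-segmentation near zero.

The same workflow is available from the shell:

```bash
segrefine phantom --out suite --n 5 --seed 0
segrefine refine  --image suite/image_phantom_0.nii.gz \
                  --mask suite/init_phantom_0.nii.gz --out refined.nii.gz
segrefine eval    --gt suite/gt_phantom_0.nii.gz --pred refined.nii.gz [--strip 5]
segrefine sweep   --config sweep.yaml --csv report.csv
```

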