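# suturevision

Quantitative analysis of the **midpalatal suture** in CBCT, for researchers
studying maxillary transverse development and the timing of rapid maxillary
expansion (RME). The ossification status of the midpalatal suture — not
chronological age alone — determines which expansion technique is
appropriate; this package implements an image pipeline that condenses the
suture's multi-slice CBCT appearance into one fused image, quantifies its
texture, and stages it into five age ranges with an explainable classifier.

## What it does

Given a CBCT volume (DICOM series or a portable `.npz` gray array) and an
expert boundary-label record, the pipeline:

1. **ROI extraction** — crops a 50×200 px suture window from every labeled
   axial slice (50 px across the suture, anterior–posterior length
   normalized to 200 px by bilinear resampling).
2. **Pairwise-merge fusion** — fuses the slice stack into one image. Each
   pair merge computes the per-pixel average `A_ij` and re-weights it by
   its deviation from the pair's mean gray `e`:

   `P_ij = A_ij · (1 + (A_ij − e) / (255 + d))`

   where `d` is an adjustment factor from the pair's maximum gray
   difference. Pairs are merged tournament-style (exactly n−1 merges in
   ⌈log₂ n⌉ rounds), which preserves contrast that direct all-at-once
   averaging would wash out. An unsharp-Laplacian operator then sharpens
   the result.
3. **Texture analysis** — six gray-level co-occurrence matrix (GLCM)
   features per fused image (correlation, contrast, homogeneity,
   dissimilarity, ASM, energy = √ASM), with per-sex Pearson/Spearman
   trends against chronological age. Homogeneity and correlation rise as
   the suture ossifies and the palate's texture becomes uniform.
4. **Age-range staging** — a residual CNN (identity-shortcut blocks,
   `x_{l+1} = ReLU(x_l + F(x_l))`; the canonical 50-layer bottleneck
   layout is available, a small basic-block variant trains in minutes on a
   CPU) classifies fused images into five ranges: 4–10, 11–12, 13–14,
   15–16, 17–23 years. The neural-network core is a compact numpy
   implementation with manual backpropagation, so every gradient —
   including the additive identity term of the residual backward pass — is
   exact and testable.
5. **Grad-CAM** — channel weights `α_k = (1/Z) Σ_ij ∂y^c/∂A^k_ij` over the
   last convolutional stage, map `L = ReLU(Σ_k α_k A^k)`, upsampled and
   alpha-blended in red over the fused image.
6. **Evaluation** — confusion matrix, per-class precision/recall/F1,
   accuracy, one-vs-rest rank-based AUC per class and their average.

Because clinical CBCT databases are private, the package includes a
seeded **phantom generator**: 512×512 axial stacks of textured bone crossed
by a sinuous, speckled suture band whose contrast, width and roughness fade
with a latent ossification parameter ω ∈ [0, 1]. Every stage of the
pipeline is tested end-to-end against these phantoms.

## Worked example

```bash
suturevision simulate --n 20 --seed 1 --out work/sim --n-slices 7
suturevision fuse --labels work/sim/labels.csv --volumes work/sim/volumes --out work/fused
suturevision features --fused work/fused --labels work/sim/labels.csv --out work/feat
```

`work/feat/features.csv` then holds one row per scan, e.g. (abridged):

```
subject_id,age_months,sex,correlation,contrast,homogeneity,...
S0000,102,F,0.141785,4496.764277,0.094584,...
S0001,127,F,0.338452,3088.927368,0.134752,...
```

(the 8.5-year-old S0000 has a rougher, less homogeneous suture window than
the 10.5-year-old S0001 — exactly the trend the features are built to
capture)

and `work/feat/age_correlations.csv` reports the per-sex trend of each
feature against age. On phantom cohorts the homogeneity and correlation
features rise monotonically with the latent ossification parameter
(Spearman ρ ≈ 0.95 at n = 200) — the texture signature of a maturing
suture. The same library calls are available in Python:

```python
from suturevision import (PhantomParams, generate_volume, extract_roi,
                          fuse_stack, texture_features)

grid, bounds = generate_volume(PhantomParams.from_ossification(0.3, seed=7))
fused = fuse_stack(extract_roi(grid, bounds))
print(texture_features(fused.pixels).homogeneity)   # 0.1055: a young suture
```

Training and explanation:

```bash
suturevision train --fused work/fused --labels work/sim/labels.csv --out work/model
suturevision evaluate --scores work/model/test_predictions.csv --out work/metrics
suturevision explain --checkpoint work/model/checkpoints/step000600.npz \
                     --image work/fused/S0003.png --out work/cam.png
```

`evaluate` writes a per-class table (precision, recall, F1, AUC, support)
plus overall accuracy and the average AUC, and one ROC curve PNG per class.

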