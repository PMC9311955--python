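# Methods

This note documents the models, numerical conventions and design choices of
the package, and what its synthetic validation does and does not show.

## Data model

A CBCT scan is a stack of 512×512 axial slices, windowed per volume to
8-bit gray by min–max rescaling (a constant volume maps to zero; the
rescale is monotone, so voxel order statistics survive). Axes are
`(axial, row, col)` with rows running anterior→posterior in-plane. DICOM
series are sorted by `ImagePositionPatient` along the axial axis, falling
back to `InstanceNumber`; non-uniform slice spacing is a warning, not an
error. Expert labels (axial extent, anterior/posterior extent, midsagittal
column, age in months, sex, optional participant id) travel in a flat CSV;
all index ranges are 0-based half-open. Ages are restricted to
[48, 288) months — 4 to 23 years, the growth window in which suture
maturation is clinically informative.

## ROI extraction

The suture window is 50 px across the suture (cropped exactly, centred on
the labeled midline) by 200 px anterior–posterior (the labeled extent,
bilinearly resampled). Output rows are transverse, anterior at column 0.
Resampling uses a pixel-centre grid: output sample `j` of an axis resized
from `n_src` to `n_out` reads source coordinate
`(j + 0.5)·n_src/n_out − 0.5`, clamped. Bilinear weights are convex, so the
ROI can never overshoot the source intensity range. The 50-px transverse
extent is cropped rather than rescaled because the suture's transverse
neighbourhood is what the texture features measure; stretching it would
distort the very statistics of interest.

## Pairwise-merge fusion

One pair merge of images `I¹`, `I²`:

    A_ij = (I¹_ij + I²_ij) / 2
    e    = mean(A)
    d    = max_ij |I¹_ij − I²_ij|          (default d_mode="max")
    P_ij = A_ij · (1 + (A_ij − e) / (255 + d)),   clipped to [0, 255]

Pixels brighter than the pair mean are amplified, darker ones suppressed,
so the enhancement term counteracts the contrast loss of averaging. Two
properties anchor the implementation: any uniform pair is a fixed point
(`A = e` annihilates the term, for every `d`), and enhancement never
changes the side of the mean a pixel is on. `d` acts as a damping term —
the more two slices disagree, the gentler the enhancement. The divisor
grouping `(A − e)/(255 + d)` is the default; the additive reading
`(A − e)/255 + d` is available via `FusionParams(grouping="additive")` but
sacrifices the fixed-point property.

A stack of n slices is merged in rounds (consecutive pairs, odd trailing
image carried forward), costing exactly n−1 pair merges. Merging pairwise
rather than averaging everything at once matters: averaging n independent
slices shrinks texture variance ~n-fold before any enhancement can act,
whereas the tournament applies enhancement at every level. The test suite
asserts the resulting variance ordering directly. All intermediate
arithmetic is float64; quantization (round half up) happens once, at the
end.

Sharpening convolves with `[[0,−k,0],[−k,1+4k,−k],[0,−k,0]]` (edges
replicated, clipped), an unsharp-Laplacian with unit DC gain: flat fields
are invariant for any k. Default k = 0.5.

## Texture features

Gray-level co-occurrence matrices are computed at offset distance 1 for
angles 0°/45°/90°/135° (conventional orientation names; the scikit-image
backend measures angles with the row axis downward, so diagonal angles are
sign-flipped internally), symmetric and normalized, 256 levels. The six
features follow the standard definitions:

    contrast      = Σ p(i,j)(i−j)²         dissimilarity = Σ p(i,j)|i−j|
    homogeneity   = Σ p(i,j)/(1+(i−j)²)    ASM           = Σ p(i,j)²
    energy        = sqrt(ASM)              correlation   = Σ p(i,j)(i−μᵢ)(j−μⱼ)/(σᵢσⱼ)

Features are averaged over the four angles for rotation robustness; energy
is the square root of the angle-averaged ASM so that energy = √ASM holds
exactly at the vector level. A constant image has undefined correlation
(zero marginal variance); it is reported as NaN with a `defined` flag
rather than silently coerced. Age association is reported per sex as both
Pearson and Spearman coefficients, with undefined cases flagged as 0.

## Age-range labels, augmentation, splits

Ages floor to whole years and map to five ranges: 4–10 → 0, 11–12 → 1,
13–14 → 2, 15–16 → 3, 17–23 → 4. Training augmentation composes small
random transforms — whole-pixel translation (≤5% of extent), tilt (≤5°),
contrast/brightness (±10%), symmetric crop (≤5%) with resize back to
50×200, and horizontal mirroring (p = 0.5) — deterministically from a
passed generator. Splits take exact per-class quotas (default 10
validation, 20 test per class) from participants whose scans all carry one
label, found by a subset-sum search so the quota is met exactly without
splitting any participant across subsets; everything else trains. With the
emulated 1006-scan cohort this yields the 856/50/100 partition. Grouping
by participant is deliberate leakage hygiene: repeat scans of one person
never span the train/test boundary.

## The residual classifier

The network is a residual CNN over 1-channel 50×200 inputs: a stem
(convolution stride 2, batch norm, ReLU, 3×3 max-pool stride 2), stages of
residual units `x_{l+1} = ReLU(x_l + F(x_l))` with identity shortcuts
(1×1 projection only where shape changes), global average pooling, and a
softmax head over five classes. Two layouts are provided:

* `NetworkSpec.resnet50()` — bottleneck blocks in counts (3, 4, 6, 3),
  widths 64→512, expansion 4. Its parameter count and 50 weight layers are
  verified against an independent arithmetic oracle, and its forward pass
  is exercised, but it is not trained in the test suite.
* `NetworkSpec.small()` — basic blocks (1, 1, 1), widths 8/16/32, 5×5
  stem, ≈20k parameters. This is the configuration used for all synthetic
  training runs; it reaches 100% held-out accuracy on well-separated
  phantom classes within ~50 steps.

The layers (convolution via im2col, batch normalization, max-pool, linear)
are implemented in numpy with hand-written backward passes, each verified
by central finite differences. The residual backward pass carries the
additive identity term — `∂loss/∂x_l = upstream·(1 + ∂F/∂x_l)` — which the
tests confirm both numerically and exactly (a zeroed branch passes
gradients through untouched). Training is SGD with momentum 0.9, L2 weight
decay on convolution/linear weights only, and an exponentially decaying
learning rate `lr·decay_rate^(step/decay_steps)` floored at
`end_learning_rate` (a linear polynomial schedule is available).
`TrainConfig` defaults (lr 1e-4, decay 0.9/4000, weight decay 1e-4, batch
50) are the reference configuration; the desk-scale synthetic runs pass
lr 0.02 explicitly because a ~20k-parameter net trained from scratch with
plain SGD needs it. Checkpoints embed parameters, batch-norm running
statistics, the architecture spec and the training config in one `.npz`.

## Grad-CAM

For class `c`, the pre-softmax score `y^c` is backpropagated to the output
`A` of the last residual stage; channel weights are the spatial means
`α_k = (1/Z) Σ_ij ∂y^c/∂A^k_ij`, and the map is `ReLU(Σ_k α_k A^k)`,
bilinearly upsampled to 50×200 and min–max normalized. With a GAP+linear
head, `α_k = w_ck/Z` exactly, which the tests assert analytically. The
overlay blends a red tint with per-pixel weight `alpha·heat` (default
alpha 0.4): a zero map returns pure grayscale. By default explanations
target the predicted class.

## Evaluation

From the 5×5 confusion matrix (rows actual, columns predicted): per class,
TP is the diagonal entry, FP the column residue, FN the row residue, TN
the remainder; precision, recall, and F1 (harmonic mean) follow, with 0/0
reported as 0 and flagged. Accuracy is the proportion of correctly
identified samples, trace/total; the alternative per-class summation
Σ_X (TP_X+TN_X)/N is reported separately as `per_class_acc_sum` because it
is a different statistic (it sums five per-class accuracies and is not
bounded by 1). ROC analysis is one-vs-rest on the softmax scores with a
rank-based (Mann–Whitney) AUC using midranks for ties — equal to
trapezoidal integration of the empirical ROC curve, which the tests check
to 1e-12 — and the summary is the arithmetic mean of the per-class AUCs;
classes absent from the truth are excluded with a warning.

## The phantom generator

`generate_volume` emulates the *data-generating situation*, not palate
anatomy: textured bone (Gaussian noise smoothed σ=1.5 around gray 170)
crossed, between labeled boundaries, by a sinuous band along the
anterior–posterior axis at the midline. A latent ossification parameter
ω ∈ [0, 1] drives every age-dependent property:

| property | ω = 0 (open) | ω = 1 (closed) |
|---|---|---|
| band Gaussian half-width | 8 px | 1.2 px |
| speckled gray deficit scale | 40 | 0 |
| band high-frequency jitter (sd) | 10 | 0 |
| interdigitation amplitude | 7 px | 1 px |
| bone noise (pre-smoothing sd) | 25 | 10 |
| smooth density field (sd, σ=12 px) | 0 | 20 |

Three modelling points matter. First, the open suture is *speckled* — a
per-volume random gap/island pattern multiplies the deficit — because a
smooth dark stripe would add large-scale structure that *raises* lag-1
texture correlation, inverting the intended trend; real young sutures are
locally rough. Second, the speckle pattern is shared across slices (it is
a 3-D structure), so it survives pairwise fusion instead of averaging
away. Third, mature bone gains a long-wavelength density field, the source
of the rising correlation feature at high ω. With these choices the full
pipeline (extract → fuse → GLCM) recovers Spearman ρ(ω, homogeneity) ≈ 0.93
and ρ(ω, correlation) ≈ 0.97 in population.

`generate_cohort` reproduces the demographic shape of a 1006-scan growth
cohort: per-year age/sex counts summing to 610 female and 396 male files,
690 participants with 1–5 repeat scans (414/245/23/7/1), ω a noisy
monotone function of age (sd 0.06 around a linear ramp over 4–23 years).
`n = 1006` uses the exact roster; other sizes resample it.

What passing phantom tests shows: the pipeline's operations are correct
and the texture/CNN stages recover a constructed ossification signal
end-to-end. What it does not show: performance on clinical CBCT, where
anatomy, scanner physics, labeling variability and the age–maturation
relationship are all far less regular than the phantom's.

## Problem sizes and numerical choices

Synthetic studies run at: 200 phantoms for texture trends; 300 fused
images (three ω levels) for classifier separability, 600 training steps;
a 250-scan five-class cohort for the end-to-end evaluation run. These
sizes were chosen so the whole validation executes in minutes on one CPU
core while leaving the measured effects far from their decision
thresholds. Ties in argmax predictions break to the lowest label;
quantization is round-half-up; GLCM requantization to fewer levels applies
only when gray values exceed the level count; all randomness flows through
explicitly passed seeds or `numpy.random.Generator` objects.

## Known limitations

* The phantom is a statistical emulation; none of its parameters are
  calibrated to real CBCT gray distributions.
* The full 50-layer network is structure-verified but not trained here —
  numpy training at that scale is impractical; the small variant stands in
  for all learning experiments.
* Fusion assumes the labeled crops are already aligned across slices;
  there is no registration step.
* Expert labels are trusted as given beyond schema/invariant validation;
  automatic suture detection is out of scope.
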