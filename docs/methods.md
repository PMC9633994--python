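# Methods

## Problem and model

The toolkit addresses longitudinal new-lesion segmentation in multiple
sclerosis: given a baseline and a follow-up FLAIR scan of the same patient,
already skull-stripped and co-registered, predict the binary mask of lesions
that appear only at follow-up. Existing lesions — including ones that grow
between time points — are deliberately *not* part of the positive class,
which is the hard part of the task: a model must suppress everything that is
merely stable or growing pathology.

The segmentation model is a 3D U-Net-style encoder–decoder with the two time
points stacked as input channels. Six resolution levels (configurable); per
level two 3×3×3 convolutions, each followed by instance normalization and
LeakyReLU (slope 0.01). The first convolution of every level below the top
is strided: (2,2,2) everywhere except the transition into the lowest level,
which uses (2,1,2) because the axial (slice-normal) axis starts at roughly
half the in-plane resolution and would otherwise collapse too fast. The
decoder upsamples with transposed convolutions whose kernel equals the
transition stride (so upsampling is exact and non-overlapping), concatenates
the encoder skip features, and refines with two further convolutions. A
1×1×1 convolution produces K = 2 class scores; output shape equals input
shape, which requires each patch axis to divide the cumulative stride
product (the forward pass checks this and names the offending axis).
Feature widths follow min(base·2^ℓ, cap) with base 32 and cap 320 at full
scale: 32, 64, 128, 256, 320, 320.

The network, its backward passes and the optimiser are implemented directly
in NumPy: convolutions via im2col + BLAS matmul, transposed convolutions as
block upsampling (exact because kernel == stride), instance normalization
with the standard normalised-activation backward. Gradients were verified
against finite differences in the unit tests. This keeps the package
dependency-light and every numerical step inspectable.

## Loss

Per patch, with softmax output ŷ and one-hot target y over classes K and
voxels I:

* soft-Dice term: −(2/|K|) Σ_k [ Σ_i ŷ_i(k) y_i(k) / (Σ_i ŷ_i(k)+y_i(k) + ε) ],
  in [−1, 0], equal to −1 exactly at a perfect prediction with both classes
  present;
* cross-entropy term: −Σ_i Σ_k y_i(k) log max(ŷ_i(k), ε), non-negative and
  zero at a perfect prediction.

ε = 1e−5 guards empty-class denominators (a patch with no lesion voxels is
the common case at <0.1% lesion fraction) and floors the logarithm; the
floor (rather than an additive offset) keeps CE exactly zero at ŷ = y.

Cross-entropy is **summed over voxels** by default, which is the objective
as written. A `ce_reduction="mean"` option averages per voxel instead,
making the Dice/CE balance independent of patch size. The sum is the default
for a second reason: under extreme class imbalance the per-voxel CE gradient
after mean reduction scales as 1/|I| and becomes negligible against the
globally-normalised Dice gradient; in short desk-scale runs this lets
training collapse into the all-background minimum, whereas the summed CE
keeps an O(1) restoring gradient at every mislabelled lesion voxel. (At full
scale, with hundreds of thousands of steps, both reductions are known to
train; the choice matters at small step budgets.)

Optimisation: SGD with Nesterov momentum 0.99, initial learning rate 0.01,
polynomial decay (1 − t/T)^0.9, batch size 2, gradient-norm clipping at 12.
All are configuration fields; epochs (1000 at full scale) and steps per
epoch are reduced for desk-scale work.

## Patch sampling and inference

Training patches (128×112×160 at full scale) are drawn uniformly with
probability 2/3 and centred on a uniformly chosen lesion voxel with
probability 1/3 (per-patch Bernoulli; cases with empty labels always draw
uniformly). Lesion-centred windows are shifted inward at boundaries rather
than padded, preserving real context; images smaller than the patch are
zero-padded symmetrically first. Both input channels are z-scored over the
whole volume before patch extraction — training and inference share this
code path, so the statistics can never disagree.

Inference tiles the volume with 50%-overlap sliding windows, averages
per-voxel foreground probabilities over windows (and over fold models, when
ensembling), and thresholds at 0.5 — for K = 2 this equals the argmax of the
mean softmax. No morphological post-processing is applied.

Fold cross-validation: a seeded permutation splits cases into n_folds
near-equal parts; each fold trains on its complement and validates
whole-volume Dice after every epoch; the checkpoint with the highest
validation Dice is kept (ties resolve to the earliest epoch).

## Augmentation

* **Axial subsampling** (imaging-aware): a 1×1×n median filter, n ∈ {2,3,4},
  along axis 2, emulating thick-slice acquisition. Even-length windows take
  the *lower* of the two middle values, so outputs stay within the input
  value set; the window covers offsets ⌈−(n−1)/2⌉…⌊n/2⌋ with edge-inclusive
  reflect padding (a one-slice volume is a fixed point).
* **CarveMix** (lesion-aware): the carve mask is M = {v : D(v) ≤ λ}, where D
  is the signed Euclidean distance transform of the donor's lesion label in
  mm (negative inside, positive outside; spacing-aware, so anisotropic grids
  carve isotropically in physical space). λ is sampled half the time as
  −|D_min|·u (an inner sub-lesion region) and half the time as (|D_min|/2)·u
  (the lesion plus a bounded dilation), u ~ Uniform(0,1]. Both channels and
  the label are fused with the same M by voxel selection, so every output
  voxel equals one parent's value exactly and the label stays binary. During
  training each sampled case is mixed with probability 0.5 with a random
  non-empty-label donor; mixing happens on the fly, before the standard
  transforms and patch extraction. No intensity harmonisation is applied
  before mixing (a z-score matching flag exists but defaults off — the
  mixing equation is applied verbatim, and the per-volume input z-scoring
  happens downstream anyway).
* **Standard set** (plumbing): per-axis mirroring (label mirrored
  identically), gamma transform on min-max-normalised intensities, additive
  Gaussian noise. Elastic deformation, rotation/scaling, Rician noise and
  the rest of the full augmentation catalogue are intentionally out of
  scope.

All transforms consume an explicit `numpy.random.Generator`, so a training
run is a pure function of (config, seed).

## Lesion-wise evaluation

Lesions are connected components (26-connectivity by default, configurable
to 6/18) with physical volume ≥ 3 mm³; the exclusion applies to both
ground-truth and predicted masks before matching. For each ground-truth
lesion g, the union P_g of predicted components touching g detects g iff
|P_g ∩ g| ≥ 0.10·|g| and |P_g \ g| ≤ 0.70·|P_g|. The outside-fraction
denominator is the detected union by default ("go outside" describes the
detection); a `outside_denominator="gt"` switch implements the alternative
reading relative to the ground-truth volume, since the rule's prose admits
both. Predicted components touching at least one detected lesion are
matched; the rest are false positives, and V_FP sums their volumes
(voxel count × voxel volume). DSC is computed on the raw voxel masks (the
volume exclusion is a detection-metric concept). Conventions: DSC with both
masks empty is 1, with exactly one empty is 0; F1 with neither ground-truth
lesions nor predictions is undefined and excluded from subset means, with
predictions but no ground truth it is 0. Cohort reports average the
new-lesion subset (DSC, F1, n_TP, n_FP, n_FN) and the no-new-lesion subset
(n_FP, V_FP) separately, and count correctly identified cases (non-zero F1,
respectively zero retained predictions).

## Synthetic phantoms

Each phantom case is an ellipsoidal "brain" (background 0 outside) with a
smooth low-frequency tissue field (mean 1.0, ~8% modulation), containing
axis-aligned ellipsoidal hyperintense lesions with a Gaussian-profile edge
(full contrast inside the ellipsoid, falloff width 0.25 of the radius).
Existing lesions appear at both time points and are scaled up by
`growth_fraction` in radius at follow-up; new lesions appear only at
follow-up and are the only voxels in the ground-truth label — grown rims are
deliberately excluded, reproducing the growing-lesion confound of real
longitudinal annotation. Placement enforces containment in the brain and
pairwise separation (including grown extents), with bounded retries; each
lesion's analytic volume 4/3·π·r_a r_b r_c serves as an oracle for the
voxel-counting metrics. Noise is additive Gaussian, drawn independently per
time point. Defaults: 48×48×64 voxels at 0.977×0.977×0.530 mm (the
anisotropic spacing typical of the emulated cohort), 3 new + 2 existing
lesions of radius 1.5–4 mm, contrast 0.6, noise σ 0.05. Cohorts derive
per-case seeds from one cohort seed and give exactly
round(fraction_no_new·n) cases an empty label.

What the phantoms do **not** emulate: MR physics (bias fields, Rician noise
statistics, partial-volume effects at tissue interfaces), anatomy (gyri,
ventricles, white/grey contrast), registration error between time points,
scanner heterogeneity, and realistic lesion morphology (confluent,
periventricular, juxtacortical shapes). Passing tests on phantoms therefore
demonstrates the correctness of the pipeline's computations and its ability
to learn a high-contrast longitudinal signal at small scale — not clinical
performance on real FLAIR data, which additionally requires full-scale
training on challenge data.

## Scales and numerical choices

Desk-scale defaults used throughout the tests and the reproduction script —
chosen so a full run stays in CPU-minutes: a 3-level network (base width 8,
cap 32), 32³ patches on 32³ phantoms, 75 training steps (3 epochs × 25
steps, batch 2), 10-case cohorts. The full-scale configuration (6 levels,
32/320 features, 128×112×160 patches, 1000 epochs × 250 steps, 5 folds) is
the package default and is exercised structurally (construction, shape and
width contracts) but not trained in the tests.

Other fixed choices: cohort median spacing uses the lower middle value for
even counts, so the target spacing is always one actually observed;
resampling maps voxel centres (shape = round(shape·spacing/target), minimum
1), trilinear for images and nearest-neighbour for labels (guaranteeing
binarity and preserving small-component topology); coordinates are 0-based
with half-open shapes and axis 2 is the axial slice-normal by convention;
NIfTI affines are carried through untouched but never used to reorient.
Checkpoints store weights, network config and fold metadata in a single
archive; training logs record per-epoch Dice/CE terms and validation Dice.

## Limitations

Pure-NumPy training is single-threaded-CPU oriented; full-scale training of
the six-level network is out of reach here and untested beyond construction.
Brain extraction, bias-field correction and registration are preconditions,
not components (an external-command hook exists in the CLI). The detection
rule implements the published thresholds with both denominator readings but
has not been cross-validated against the reference evaluation binary, which
is not redistributable; small discrepancies in ambiguous configurations
(e.g. chains of predictions bridging lesions) are possible.
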