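# Methods

## Model and training procedure

The segmentation problem is 4-class per-pixel classification of short-axis
cardiac MR slices (background / RV / MYO / LV), trained slice-by-slice.
The model is an encoder-decoder (U-Net family) with one shared encoder E
and three decoders of identical architecture and independent weights:

- **D_S** (supervised) is trained with pixel-wise cross-entropy on the
  labeled pool — the original labeled slices plus their cut-and-mix
  augmented copies.
- **D_D** (dropout path) and **D_N** (noise path) decode perturbed copies
  of the bottleneck feature and are trained, together with E, to match the
  prediction of the supervised path under mean-squared error on the
  probability maps. The supervised prediction is a *fixed target*: no
  gradient from the consistency term reaches D_S. The consistency pool is
  the unlabeled slices, their cut-and-mix copies, and the cut-and-mix
  copies of the labeled slices.

The consistency weight follows λ(epoch) = min(λ_max, λ_max·e^{2·epoch/stop−1})
with λ_max = 0.4: it starts at λ_max/e, rises exponentially, and saturates
at epoch = stop/2. `stop` defaults to the run length. The printed form of
this schedule is typographically ambiguous; the reading above (exponent
2·epoch/stop − 1) was chosen because it gives a finite warm-start value
λ_max/e at epoch 0 and a cap reached midway, which matches how exp-ramp
consistency weights are conventionally used. The exponent convention is a
single place in `objective.lambda_schedule` should an alternative reading
be needed.

One *epoch* is one pass over the labeled pool; each step draws a labeled
batch (batch size 4) and an equal-size batch from the consistency pool,
sampled with replacement. Cut-and-mix pairings are regenerated every epoch.
Optimization is Adam (default moments) at 5·10⁻⁴, halved at epochs
200/1000/1500/1800/2100; the desk-scale 150-epoch runs therefore use a
constant learning rate, which is the schedule's prescription, not an
override. Standard augmentation is an affine transform (scale 0.9–1.1,
optional shear, rotation ±15°) plus an intensity shift ±0.1 with
re-clipping to [0,1]; geometry is shared between image (bilinear) and mask
(nearest-neighbor).

All stochastic draws flow through named, independent streams derived from
one seed (mixing, batch order, augmentation, perturbations — separately
for the labeled and unlabeled sides). Two consequences are tested: runs
are bit-reproducible, and a semi-supervised run with λ_max = 0 follows the
exact weight trajectory of the supervised-only trainer.

## Perturbations

- **Spatial dropout P_D**: a rate r ~ U(0.10, 0.40) is drawn per forward
  pass and round(r·h·w) spatial positions of the bottleneck are zeroed,
  the same positions in every channel, without survivor rescaling (this is
  a consistency perturbation, not train-time regularization). Zeroing is
  pixel-wise; contiguous-region dropout is a possible variant the default
  does not implement.
- **Gaussian noise P_N**: i.i.d. N(0, σ²) with σ = 0.1 in absolute feature
  units (configurable); the magnitude is a free parameter of the method.
- **Cut-and-mix P_C**: 2×2 equal blocks, k ∈ {1,2} blocks swapped at
  corresponding positions, identical swap on masks. Pairing is random
  within a pool per epoch; labeled is never paired with unlabeled (the
  mixed label would be undefined); an odd leftover sample passes through
  unmixed. The operation conserves the pixel multiset of each pair and is
  its own inverse, both property-tested.
- Feature perturbations touch only the bottleneck (deepest) feature; skip
  connections reach the auxiliary decoders unperturbed. This is the
  minimal reading of "perturb the encoder output"; perturbing skips too is
  a plausible variant left out of scope.

## Backbone and the frozen full-scale configuration

The backbone is a depth-5 U-Net, widths doubling from `base_width`, two
convolution units per level, instance normalization + ReLU after every
3×3 convolution, parameter-free bilinear ×2 upsampling, and a 1×1
four-class classifier with softmax. The ghost variant replaces every
interior 3×3 convolution by a Ghost block (primary 3×3 conv to b/s
channels; s−1 depthwise 3×3 "cheap" transforms; identity group concatenated
first; s = 4). The 1×1 classifier and resampling stay standard — replacing
the classifier would break s-divisibility for 4 classes.

Per-level widths of the reference architecture are not published; only
aggregate model sizes are. The default full-scale configuration was
therefore calibrated **once** and frozen: `base_width = 52` (widths
52…832) with decoder first-conv widths (1152, 584, 296, 148), chosen so
the standard-convolution network reproduces the reference sizes exactly —
35.5 M test-time (E + D_S) and 81.5 M training-time (E + 3 decoders)
parameters. Those two constraints pin the encoder/decoder split
(E ≈ 12.4 M, D ≈ 23.0 M), which is why the decoder blocks are wider than
a textbook U-Net decoder. Bilinear upsampling (a standard option for this
architecture family) is part of the frozen calibration: transposed-conv
upsampling would put ~2.5 M parameters in layers the ghost substitution
cannot reduce and drag the standard/ghost ratio below the observed ~4×.

With that configuration frozen, uniform ghost substitution yields
8.9 M / 20.5 M (test / train). The corresponding reference figures
(8.7 M / 25.2 M) are **not** reachable exactly: a Ghost block with s = 4
reduces a 3×3 convolution's parameters by strictly less than 4×, so a
35.5 M standard network cannot drop below ≈ 8.9 M, and the four published
numbers are mutually inconsistent under encoder + k·decoder accounting.
The package reports what its networks actually contain; the ratio bands
(params ≈ 3.98×, FLOPs ≈ 3.96× at 1×160×160) hold.

FLOP convention: 1 MAC = 2 FLOPs, counted for conv / depthwise /
transposed-conv layers only; normalization, activations, pooling,
interpolation and bias adds are excluded. Absolute FLOPs are therefore
convention-bound and comparisons should use ratios; the report carries the
convention tag.

## Metrics

Dice is the standard 2|X∩Y|/(|X|+|Y|) reported in percent (an alternative
"union" form that divides by |X∪Y| exists behind a flag for audit — it
exceeds 1 on partial overlap and is not used). Conventions: two empty
regions → 1, one empty → 0. Hausdorff is the symmetric max-min Euclidean
distance over *full* foreground point sets (not boundaries), computed on
per-subject 3D slice stacks with physical (slice, row, col) spacing in mm;
a structure empty on either side has no defined Hausdorff and is excluded
from means with a warning. Per-subject 3D (rather than per-slice 2D)
aggregation was chosen because test metrics are reported per subject.
After resizing to the network input, in-plane spacing is rescaled by
original_size/target_size.

## Synthetic phantom

Each slice contains a bright LV disk (intensity mean 0.80) inside a darker
myocardial annulus (0.35) with an RV crescent (0.70) hugging the annulus,
on a dark background (0.20); pixel noise is N(0, 0.05²) with clipping to
[0, 1]. Geometry (center, radii, crescent direction) is drawn per subject;
radii scale linearly across the 5-slice stack (×0.70 apex → ×1.10 base).
The intensity separation is chosen so the task is learnable but not
trivial: plain thresholding reaches Dice ≈ 0.7–0.8 on LV, leaving
headroom that network quality can close, while RV vs LV (0.70 vs 0.80)
genuinely requires spatial context. The phantom emulates the statistical
structure the method assumes — subject-level geometry variation,
labeled-few/unlabeled-many splits, class-conditional intensities — but none
of the physics of MR (coil bias fields, partial volume, motion, through-plane
anisotropy), so passing desk-scale tests demonstrates the machinery and the
direction of the semi-supervised effect, not clinical-grade performance.

## Desk-scale benchmark and problem sizes

The phantom benchmark uses 52 subjects × 5 slices at 64×64 (2 labeled /
30 unlabeled / 20 test), a tiny ghost backbone (depth 3, base width 8,
≈ 50 k parameters), 150 epochs, λ ramp stop = 150, three seeds, with the
supervised-only baseline trained on the same labeled subjects with the
same standard augmentation (no cut-and-mix, matching the baseline's
definition). These sizes keep a full 3-seed paired run in the tens of
minutes on one CPU core while preserving the regime of interest (m ≫ n,
subject-level splits). The expected outcome — and what the acceptance
suite asserts — is directional: the cross-consistency model beats the
baseline's mean test Dice in at least 2 of 3 seeds. Absolute Dice values
on the phantom are not comparable to real cine-MR results.

## Numerical choices and degenerate inputs

- float32 throughout; probability clamping at 1e-7 inside the CE log.
- Consistency MSE is computed on post-softmax probabilities (bounded
  targets), averaged over pixels *and* classes.
- Instance-norm ε = 1e-5; statistics are per sample and channel at train
  and eval time, so evaluation is batch-size independent.
- Min-max intensity rescaling is per slice; a constant slice maps to all
  zeros rather than NaN.
- Odd image sizes are rejected at preprocessing (the 2×2 block grid and
  pooling require even sizes); inputs must be divisible by 2^(depth−1).
- Max-pool backward routes gradient to the argmax (first index on exact
  ties).
- A non-finite loss aborts training with a diagnostic rather than
  continuing silently.
- Checkpoints are single-file `.npz` archives holding config, weights,
  optimizer state, epoch and seed; reloading reproduces evaluation
  bit-identically.

## Known limitations

- CPU-only and desk-scale by design; full-scale 3000-epoch training on
  real cine-MR data is out of scope, as are 3D convolutions, pretrained
  weights, other lightweight blocks, and uncertainty/adversarial variants.
- The ghost-variant aggregate sizes differ from the reference figures for
  the architectural reason given above.
- The unlabeled pool uses the annotated-phase frames only; full cine
  sequences are not modeled.
- Hausdorff is computed on full point sets, as defined; a boundary-only
  variant (common in some toolkits) would give smaller distances.
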