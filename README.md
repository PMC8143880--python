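# lccnet

Semi-supervised segmentation of short-axis cardiac MR images with a
**l**ightweight **c**ross-**c**onsistency **net**work: a Ghost-module U-Net
backbone whose shared encoder feeds three independent decoders — one
supervised, two trained to agree with it under feature perturbations — so
that a model trained on a handful of annotated subjects can still exploit a
large pool of unannotated ones.

The package is aimed at researchers studying annotation-efficient cardiac
segmentation (left ventricle LV, right ventricle RV, myocardium MYO) who
want a fully inspectable, CPU-only reference implementation with exact
complexity accounting, plus a synthetic phantom so every part of the
pipeline runs end to end without any dataset download.

## Model

Given labeled slices 𝒟ₗ = {(xᵢ, yᵢ)} (n slices from K subjects) and many
unlabeled slices 𝒟ᵤ (m ≫ n), the network is

- a shared encoder **E** and three architecturally identical decoders
  **D_S**, **D_D**, **D_N** with independent weights;
- prediction paths f_S = D_S∘E, f_D = D_D∘P_D∘E, f_N = D_N∘P_N∘E, where
  P_D is 10–40 % spatial dropout and P_N additive Gaussian noise, both
  applied to the bottleneck feature;
- an input-space perturbation P_C (*cut-and-mix*): two images are split
  into a 2×2 grid of equal blocks and one or two corresponding blocks are
  swapped, with identical swaps on the label masks, producing augmented
  pools 𝒟ₗ′ and 𝒟ᵤ′.

Training minimizes

```
L = L_S + λ(epoch) · L_U
L_S = mean CE(f_S(x), y)                 over 𝒟ₗ ∪ 𝒟ₗ′
L_U = mean [ d(f_S(x), f_D(x)) + d(f_S(x), f_N(x)) ]   over 𝒟ᵤ ∪ 𝒟ᵤ′ ∪ 𝒟ₗ′
λ(epoch) = min(λ_max, λ_max · e^(2·epoch/stop − 1)),  λ_max = 0.4
```

with d the mean squared error between probability maps and the f_S output
treated as a fixed target (stop-gradient). The lightweight backbone
replaces every interior 3×3 convolution by a Ghost block: a primary conv
producing b/s channels plus s−1 cheap depthwise 3×3 transforms (s = 4),
cutting the test-time network from 35.5 M to 8.9 M parameters.
Evaluation uses the Dice overlap 2|X∩Y|/(|X|+|Y|) (%) and the symmetric
Hausdorff distance (mm), per structure and subject.

Everything runs on plain numpy (plus numba-JIT inner loops): the layers,
their backward passes and Adam live in `lccnet.nn`.

## Worked example

```bash
# 1. synthesize a phantom cohort: 52 subjects x 5 slices, 64x64
lccnet synth --out data/phantom --subjects 52 --slices 5 --size 64 --seed 0

# 2. train the cross-consistency model (tiny ghost backbone, desk scale)
cat > tiny.yaml <<EOF
backbone: {depth: 3, base_width: 8, block_kind: ghost}
train:    {max_epochs: 150, lambda_stop: 150}
EOF
lccnet train --data data/phantom --out runs/lcc --model lccnet \
             --config tiny.yaml --k 2 --test-count 20 --seed 1

# 3. evaluate on the 20 held-out subjects
lccnet eval --checkpoint runs/lcc/checkpoint.npz --data data/phantom \
            --split runs/lcc/split.json --out runs/lcc/eval
```

The training command echoes its settings
(`lccnet: lr=0.0005 batch=4 epochs=150 lambda_max=0.4 seed=1`) and the
evaluation prints per-structure test-set means — Dice overlap in percent
and Hausdorff distance in mm, averaged over the 20 held-out subjects:

```
   RV: Dice 79.8 %  HD 13.31 mm
  MYO: Dice 72.5 %  HD 21.18 mm
   LV: Dice 80.7 %  HD 12.92 mm
 mean: Dice 77.7 %  HD 15.80 mm
```

The same commands with `--model baseline` (supervised-only training of a
single encoder-decoder on the 2 labeled subjects, standard augmentation
only) print a distinctly lower score on the same split —

```
   RV: Dice 65.0 %  HD 19.17 mm
  MYO: Dice 55.1 %  HD 34.71 mm
   LV: Dice 61.7 %  HD 14.80 mm
 mean: Dice 60.6 %  HD 22.89 mm
```

— a +17-point mean-Dice gain from the unlabeled pool, which is the
semi-supervised effect the method exists for. Desk-scale runs vary
noticeably across seeds and data splits (a ~50 k-parameter network, 10
labeled slices, 150 epochs); the acceptance benchmark below therefore
checks the *direction* of this gap over three seeds rather than any
absolute score.

The complexity table of the full-scale architecture:

```bash
$ lccnet complexity --size 160
input (1, 160, 160); convention: 2 FLOPs per MAC; conv/depthwise/transposed-conv only
block kind              params train   params test   FLOPs train    FLOPs test
standard                      81.5 M        35.5 M       177.3 G        64.9 G
ghost                         20.5 M         8.9 M        44.8 G        16.4 G
```

The ghost substitution shrinks the deployed network (E + D_S) by ~4.0× in
both parameters and FLOPs.

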