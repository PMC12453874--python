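# Methods

## Problem setting

Binary lesion-versus-background segmentation of 2-D medical images
(dermoscopy, endoscopy, breast ultrasound, H&E gland histology are the
motivating modalities). Input is an RGB image scaled to [0,1]; output is a
per-pixel foreground probability, thresholded at 0.5 for evaluation.

## Architecture

The network is a five-stage U-shaped encoder–decoder. Spatial size halves
five times in the encoder (inputs must be divisible by 32) and is restored
symmetrically in the decoder; each decoder stage fuses the mirrored encoder
feature through a skip connection (channel concatenation followed by a 1×1
convolution; additive fusion is available behind `skip_mode="add"`).

Three stage types appear:

**Local-global information processing block (LGIPB).** A densely connected
four-convolution unit. With input x_in:

    x1 = Conv3x3(x_in)                                  (bare: no BN/activation)
    x2 = PReLU(BN(Conv3x3(x1)))
    x3 = PReLU(BN(Conv3x3(cat(x1, x2))))
    x4 = PReLU(BN(Conv3x3(cat(x1, x2, x3))))
    out = PReLU(BN(Conv3x3(x4)))

The inner widths are fixed at 12/12/24 so the dense trace is
12 → 12 → 24 → 48 channels at every stage, independent of the stage's
input/output width; the final convolution maps 48 to the stage width.
PReLU carries one learnable negative slope per channel, initialised at
0.25. The first three encoder stages hold two LGIPBs each, followed by
2×2 max-pooling.

**Shifted-MLP stage.** The two deepest encoder stages (and the two deepest
decoder stages) are tokenized MLP blocks entered through a stride-2 3×3
patch-merging convolution. One block computes

    x + fc2(shift_H(drop(GELU(DWConv3x3(fc1(shift_W(LN(x))))))))

where shift_* partitions the channels into 5 groups and displaces group g
by g−2 pixels along one spatial axis (zero fill), fc1 expands the token
dimension by 4, and the depthwise 3×3 convolution mixes local context in
the expanded space. Token dimensionality is preserved end to end.

**Efficient multi-scale reconstruction attention (EMRA).** Channel
attention followed by multi-scale fusion. The attention path is
global average pooling → a bias-free 1-D convolution across the channel
descriptor → sigmoid; its kernel size adapts to the channel count c as

    t = floor(|log2(c) + b| / γ),   k = t if t odd else t + 1   (k ≥ 1)

with γ = 2, b = 1 by default. The reweighted map feeds four parallel
convolutions with kernels 1/3/5/7 (each C_in → C_in, same padding), whose
concatenation (4·C_in channels) is fused to C_out by a 1×1 convolution.
EMRA modules sit in decoder stages 2–5, operating on the fused
(post-skip) features and preceding the stage's plain convolution.

**Ablation variants.** `baseline` replaces every LGIPB with a single plain
3×3 convolution (+BN+ReLU) and removes every EMRA; `baseline_lgipb` and
`baseline_emra` toggle the two module families independently.

### Stage widths and the parameter anchor

The published description pins a single architectural number: 5.51 M
trainable parameters. The three convolutional-stem widths follow the
tokenized-MLP family convention (16, 32, 128); the two MLP-stage widths
were then calibrated by a grid search over (w4, w5) so that the assembled
full model counts 5.51 M to two decimals. The frozen default is
(16, 32, 128, 220, 304) → 5,508,967 parameters. Convolutions followed by
batch normalisation carry no bias term; the bare first LGIPB convolution
keeps its bias.

## Objective and metrics

Training minimises the smoothed squared-denominator Dice loss on the
sigmoid of the final output only (no deep supervision):

    DL(p, g) = 1 − (2 Σ p_i g_i + ε) / (Σ p_i² + Σ g_i² + ε),  ε = 1e−5

ε may lie in [0,1]; the default keeps the empty-prediction/empty-mask limit
at DL = 0 and the gradients finite for negative samples. Evaluation
computes Dice, IoU, recall and precision per image from the thresholded
confusion counts and averages across images (per-image computation is the
unit of analysis, matching the significance protocol below). An image with
no foreground in either prediction or truth scores 1.0 on all four metrics
by convention; this convention is a documented choice. Model comparison
uses a two-sided paired t-test on per-image IoU vectors; the protocol
helper subsamples 30 images at random before testing.

## Training regime

Adam (β = 0.9/0.999, ε = 1e−8, no weight decay, no clipping) with a
cosine-annealed learning rate stepped per epoch,

    lr(e) = lr_min + (lr0 − lr_min)(1 + cos(π e / E)) / 2,

defaults lr0 = 1e−4, lr_min = 0, E = 400 epochs, batch size 8, seeded
shuffled batching, random rotation/flip augmentation available at load
time. The last-epoch weights are checkpointed (no validation subset is
carved out of the 80/20 split). Runs are bit-reproducible from the seed:
weight initialisation, batching, augmentation and the synthetic data all
derive from it.

The 80/20 split uses half-up nearest-integer rounding of 0.8·n (612 →
490/122, 2594 → 2075/519, 210 → 168/42, 165 → 132/33), applied after a
seeded permutation; an explicit stem-list split file is also accepted.

## Numerical core

No GPU framework is used: the package carries a small reverse-mode
automatic-differentiation engine over float32 NumPy arrays
(`lgmanet.nn`). Stride-1 convolutions run as one BLAS matmul per kernel
offset accumulated over shifted views of the padded input (cheaper in both
time and memory than im2col at these shapes); strided patch-merging
convolutions use im2col; batch norm, PReLU, LayerNorm, max-pooling,
half-pixel bilinear 2× resampling, the axial channel-group shift and the
channel-descriptor 1-D convolution have hand-derived adjoints, each
verified against central finite differences in the test suite. Batch-norm
statistics use momentum 0.1 and ε = 1e−5; evaluation always runs with
running statistics. Max-pool ties resolve to the first maximal element.
All blocks accept degenerate 1×1 spatial inputs.

## Synthetic fixture generator

The generator emulates lesion-like images at desk scale: masks are unions
of 1–3 radially Fourier-perturbed ellipses (foreground fraction kept
within 5–45 %), images place a bright foreground (background level 0.35,
contrast 0.45 by default) over smooth large-scale shading plus fine
texture, with per-channel tint and pixel noise. Optional artifacts mirror
the failure modes discussed for the real benchmarks: dark curvilinear
hair-like streaks, rectangular patch occluders, multiplicative speckle,
and Gaussian boundary blur. Pair i of a fixture derives its RNG from
(seed, i), so datasets are bitwise-reproducible and individual pairs can
be regenerated independently.

What the generator does **not** model: anatomical texture statistics,
modality-specific noise (ultrasound speckle correlation, histology stain
variation), multi-object scale diversity, or annotation noise. Passing the
desk-scale checks therefore demonstrates that the architecture, losses,
and pipeline are wired correctly and can fit coherent lesion-like
structure — not that published benchmark accuracy transfers.

## Desk-scale study fixtures

Two frozen fixtures exercise the pipeline end to end on one CPU:

* **Overfit fixture** — 8 clean pairs at 96×96; 300 Adam steps at batch 2,
  lr0 1e−3 cosine-annealed. The model is expected to reproduce its own
  training masks (train and eval Dice > 0.9). The raised fixture learning
  rate reflects the tiny problem size; the paper-scale default (1e−4,
  batch 8, 400 epochs) remains the `TrainConfig` default.
* **Ablation fixture** — 40 pairs at 96×96 with low contrast (0.22) and
  all four artifact kinds, 6 epochs at batch 4 per variant, identical
  seed and split across the four wirings. Fixture sizes were chosen once
  for CPU-minute runtimes; they are study conditions, not tuning knobs.

## Known limitations

* CPU-only; a 400-epoch full-resolution run of the default model is out of
  desk scale by design.
* Binary segmentation only (num_classes = 1); no multi-class Dice.
* No boundary metrics (Hausdorff/ASSD) and no multiple-comparison
  correction in the significance helper — raw p-values are reported.
* The shifted-MLP stage follows the tokenized-MLP reading of the stage
  description (axial shift + depthwise convolution between projections);
  alternative shift orderings would be architecture-equivalent in
  parameter count but not bit-identical.
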