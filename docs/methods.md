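# Methods

## The model

MBSNet is a fully-convolutional binary segmentation network for medical
images (dermoscopy, endoscopy, ultrasound, CXR, MRI) that learns local and
global image structure in two parallel encoder branches and fuses them in a
shared decoder.

**Branch L (local)** is a five-level encoder with one 3×3
convolution–BN–ReLU per level and channel widths 16, 32, 64, 128, 256,
downsampled between levels by 2×2 stride-2 max pooling
(320 → 160 → 80 → 40 → 20 for a 320×320 input).  Each level is refined by a
*parallel residual mixer* (PRM) and re-weighted per channel by a
squeeze-and-excitation (SE) gate.

The PRM combines two shape-preserving paths and a residual connection:

    Y = f3x3( concat( fconv(maxpool3x3_s1(X)),  GELU(LN(DW3x3(f1x1(X)))) ) ) + X

- the pooled path applies a stride-1, window-3, padding-1 max pool (so the
  residual addition stays well-formed) followed by a convolution;
- the depthwise path applies a 1×1 convolution, a per-channel 3×3 depthwise
  convolution, layer normalization *over the channel axis at each spatial
  location*, and GELU;
- the concatenated 2C channels are fused back to C by a 3×3 convolution.

The convolution on the pooled path uses a 3×3 kernel.  With that choice the
PRM contributes ≈28·C² parameters per level, which reproduces the published
per-component complexity increments of the architecture almost exactly
(+2.45 M parameters / +3.73 G MACs across the five levels); a 1×1 pooled-path
convolution would fall ~30 % short of both printed increments.

**Branch G (global)** has only three blocks (widths 16, 32, 64) and
downsamples only twice, by 2×2 *average* pooling (320 → 160 → 80), so the
global stream never compresses below 1/4 resolution.  Each block is a
bottleneck `1×1 → dilated 3×3 → 1×1` (each with BN+ReLU).  The dilation rates
follow a multi-grid schedule: rate_i = r · multi_grid[i] with r = 2 and
multi_grid = (1, 2, 4), i.e. rates 2, 4, 8.  Before each block the pooled G
stream is concatenated with the same-resolution branch-L level output
(post-SE) and reduced by a 1×1 convolution, so the global stream is
continuously re-supplied with local detail.  A *spatial attention module*
(SAM) closes the branch:

    a = softmax_C( W2 GELU(W1 gap(X)) )        # channel attention, Σ_c a_c = 1
    S = Σ_c a_c · V_c,  V = 1×1 conv(X)        # single-channel context map
    Y = X + S                                  # broadcast over channels

The softmax guarantees the channel weights form a convex combination, so the
context map S is a data-dependent average of value channels; with V ≡ 1 the
context is exactly 1 everywhere.

**Branch F (decoder)** upsamples the deep L features with skip connections
(level 5 → 4 → 3, widths 256 → 128 → 64, concat + 3×3 reduction) to 1/4
scale, where the L stream meets the G stream (64 channels each).  Two
*feature cross-fusion blocks* (FCFB) then carry both streams to full
resolution; in each, every stream is channel-projected and bilinearly
upsampled ×2, and the upsampled convolution of the *other* stream is added:

    O_G = up(proj(Y_G)) + upconv(Y_L),   O_L = up(proj(Y_L)) + upconv(Y_G)

Both FCFB stages keep 64 channels per stream; the head concatenates the two
full-resolution streams (128 channels), reduces with a 3×3 conv to 16
channels (BN+ReLU) and predicts one logit channel with a 1×1 convolution.
The network emits raw logits; the sigmoid lives in the loss and metrics
layer for numerical stability.

### Width calibration

The published description fixes the branch widths of L and G and the
multi-grid rates, but leaves the decoder and FCFB widths open.  Those widths
were fixed once against the published complexity budget: with the decoder
described above the ablation configuration with PRM/SE/SAM disabled has
1.383 M parameters (published: 1.38 M) and the full model has 3.886 M
parameters / 10.906 G MACs at 320×320 (published: 3.98 M / 10.68 G, i.e.
agreement within ~2.5 %).  A halving FCFB (64 → 32 → 16, 1×1 head) was
considered and rejected: it lands ~23 % below the published parameter count
and ~45 % below the published MAC count.

### Complexity accounting

`count_parameters` sums all learnable tensors.  `count_macs` traces one
forward pass and counts Cout·H·W·Cin·k²/groups multiply–accumulates for each
convolution and Fout·Fin for each linear layer; normalization, activations
and pooling are not counted, and MACs are reported in units of 10⁹ ("G").

## Loss and metrics

Training minimizes `L = 0.5·BCE + Dice` with BCE evaluated in logit form
(`mean(softplus(z) − z·t)`) and `Dice = 1 − (2Σpg + ε)/(Σp + Σg + ε)`,
ε = 1.0, p = sigmoid(z).  Targets must be strictly binary.

Evaluation binarizes probabilities at 0.5 (the boundary maps to foreground)
and computes exact integer confusion counts per image.  Reported metrics,
each ×100: IOU = TP/(TP+FP+FN), F1 = 2PR/(P+R), precision, recall,
specificity, and G-mean = √(recall · specificity).  Dataset values are
macro averages (unweighted mean over per-image values); pooled-pixel micro
averages are available via `evaluate_dataset(..., micro=True)`.  Degenerate
conventions: empty ground truth with empty prediction scores 100 on all
metrics (flagged `empty_pair`); empty ground truth with a non-empty
prediction scores 0 on IOU/F1.

## TOPSIS ranking

Model comparison uses classic TOPSIS with Euclidean (vector) column
normalization, equal weights (1/3 per criterion), and all three criteria
(F1, IOU, G-mean) treated as benefit.  Scores are `d⁻/(d⁺+d⁻)` against the
candidate-set ideal/anti-ideal; a model worst on every criterion scores
exactly 0 and one best on every criterion scores exactly 1.  Ranks are
descending competition ranks (ties share the smaller rank).  If all rows are
identical, scores are defined as 0.5 and flagged.  The published five-model
benchmark tables are shipped as data (`topsis.PUBLISHED_BENCHMARKS`); only
variant-invariant facts of the published TOPSIS column (exact zeros, rank
orderings, rank averages) are asserted, because the published score values
themselves are not reproducible by any single candidate-set TOPSIS variant.

## Training recipe

Adam (β = 0.9/0.999, no weight decay), batch size 4, initial learning rate
1e-3 cosine-annealed per epoch to exactly 1e-5 at the final epoch (no warm
restarts), horizontal/vertical flips (p = 0.5 each) and random crop-resize
(retained side fraction 0.8–1.0) as augmentation, images resized to the
network input size and normalized by the dataset channel mean/std recorded
in the dataset manifest.  Validation runs every epoch; the checkpoint with
the best validation IOU (selectable: F1) is retained.  Every random choice
(shuffling, augmentation, initialization) derives from the configured seeds,
so identical seeds give bitwise-identical training histories.

## Synthetic data

The generator emulates single-foreground lesion segmentation data: masks
are unions of 1–3 smooth closed blobs (a disc whose radius is modulated by a
random Fourier series of order 5, amplitude 0.25, clipped to [0.3, 2.0]×),
with blob radii drawn from 12–30 % of the image side and centers in the
middle half of the frame.  Images are a constant background (0.35) plus a
foreground contrast shift (+0.3, slightly tinted per channel), a Gaussian
blur of the boundary (σ = 1.5 px), additive Gaussian noise (σ = 0.05), and
optionally multiplicative speckle (strength 0.25) for ultrasound-like
texture.  These defaults produce clearly learnable but non-trivial data:
boundary localization, not detection, is the hard part, matching the role
the real benchmarks play for the published network.

What the synthetic data does *not* model: anatomical context and distractor
structures, heavy class imbalance, acquisition artifacts, inter-annotator
noise, and multi-scale lesions far beyond the configured radius range.
Passing the synthetic-data tests therefore demonstrates that the
architecture, loss, optimization and bookkeeping work end to end — not that
the network reaches any particular accuracy on real clinical data.

## Numerical choices

- All arithmetic is float32.  Spatial activations are stored channel-last
  (NHWC) internally so convolutions run as strided stacked GEMMs without
  layout copies; the public interface is channel-first (NCHW).
- Convolutions are stride-1 with 'same' padding (pad = dilation·(k−1)/2);
  all downsampling is explicit pooling.
- Batch normalization: momentum 0.1, ε = 1e-5, biased variance for the
  batch, unbiased for the running estimate (training mode uses batch
  statistics, inference mode running statistics).
- Bilinear ×2 upsampling uses the half-pixel-center convention (corners not
  aligned), realized with exact 1/4–3/4 tap weights and clamped edges, so a
  constant map upsamples to the same constant.
- Max-pool gradients are distributed to *every* position attaining the
  window maximum (ties are measure-zero for continuous activations).
- Initialization is Kaiming-uniform (bound √(6/fan_in)) from a single
  seeded generator consumed in fixed construction order; BN gain 1, offset
  0; biases 0.  Parameter counts and initial weights are pure functions of
  the configuration.
- Checkpoints are `.npz` archives of all parameters, running statistics and
  the JSON-serialized configuration; save → load round-trips bit-exactly.

## Problem sizes in the test suite

The suite exercises the full 320×320 geometry only where the published
complexity figures require it (forward shape and MAC trace).  Training
tests run at 32×32 (plumbing, determinism) and the learning smoke test at
the published desk-scale setting: 8 synthetic 128×128 images used as both
train and val, 150 epochs, batch 4, which overfits to train IOU > 80 and
validates the optimization loop end to end.

## Known limitations

- Only stride-1 convolutions with kernels 1 and 3 and ×2 bilinear
  resampling are implemented — exactly what this architecture needs.
- No GPU or mixed precision; throughput is BLAS-bound on CPU (a 150-epoch
  desk-scale smoke run takes minutes, real-dataset training is out of
  scope).
- Single foreground class (1 logit channel); no deep supervision or
  test-time augmentation.
- The published TOPSIS score column cannot be reproduced exactly (see
  above); ranking structure is reproduced instead.
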