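# Methods

## Model

The network is a four-stage convolutional classifier for 224×224×3 images.
Its distinguishing component is a pooling-based attention gate: the sigmoid
of the elementwise product of a 3×3 average-pooled and a 3×3 max-pooled copy
of the (batch-normalized) feature map. Because the average pool tracks the
neighborhood load and the max pool tracks the local peak, the product is
large only where a pixel is strong both absolutely and relative to its
surroundings; the sigmoid maps this to a (0,1) gate with no trainable
weights. The gate is depth-concatenated with the normalized input, pooled
once more, projected back to F channels, and added residually. A grouped
inverted bottleneck (expand ×4 → GELU → compress, identity residual)
follows, the convolutional analogue of a transformer feed-forward block.
Downsampling concatenates strided average- and max-pooled maps (2F channels)
and adds a strided grouped 2×2 convolution before one GELU, so neither
peak-routing nor mean-routing alone decides what survives the resolution
drop. The head is global average pooling plus one fully connected layer with
softmax.

Structural choices that the architecture description leaves open, fixed
here:

- The patchify convolution and its batch norm in the stem are computed once
  and shared between the bottleneck branch and the residual branch.
- The two pooled maps in the attention gate are fused by elementwise
  (Hadamard) product — the only shape-consistent reading — not a matrix
  product.
- All 3×3 pools are stride 1 with same-padding (pad 1), which is the only
  shape-preserving choice consistent with the published stage shapes.
  Average pooling divides by the full 3×3 window, with padded entries
  counting as zeros.
- One batch-norm instance per block normalizes the block input and feeds
  all three of its appearances in the attention equations; the inverted
  bottleneck has its own.
- Grouped-convolution group counts: 4 for every 1×1 expansion (stem and
  blocks), 2 for the 2×2 downsampling kernels. With the sharing rules above
  this yields 6,332,554 trainable parameters at 10 classes and 7,093,864 at
  1000 classes, i.e. the intended 6.3 M / 7.1 M budget; one TNV2 block at
  width F costs 7F² + 10F.
- Channel-concatenation order: the first-listed operand (the gate; the
  average-pooled map) occupies the lower channel indices. Fixed for
  checkpoint portability.
- Odd spatial sizes at a downsampling stage raise an error rather than being
  silently padded; 224 = 4·2³·7 keeps every published stage even by
  construction. A consequence worth knowing: a 112×112 input is valid for at
  most three stages, because the fourth stage would have to halve 7×7.

## Numerical conventions

Batch norm uses eps = 1e-5; running statistics are updated with momentum 0.1
(`running = 0.9·running + 0.1·batch`), the running variance from the
unbiased batch estimate; running statistics are buffers, not trainable
parameters. GELU is exact (erf-based). Weight initialization is He fan-in
normal for convolutions and the FC layer, zero biases, batch-norm scale 1 /
shift 0, drawn from a single `numpy` generator seeded from the network
config, so construction is deterministic. Forward passes in evaluation mode
are deterministic and bit-stable under checkpoint round-trips (checkpoints
store the exact float32 arrays plus the config). Softmax and cross-entropy
are computed with max-subtraction; probability ties in prediction resolve to
the lower class index.

The network, its gradients, and the optimizer are implemented on numpy
arrays with a minimal reverse-mode tape (`poolattnet.autograd`):
convolutions via im2col/matmul per group, poolings via sliding windows with
argmax routing for the max-pool backward, and batch-norm backward
differentiating through the batch statistics in training mode. Gradients
accumulate on every graph node, which is what lets Grad-CAM read the
gradient of an intermediate activation.

## Training

The default recipe is SGD with momentum 0.9, 30 epochs, batch size 128,
learning rate 0.01, L2 penalty 1e-4, an 80:20 stratified train/validation
split, and checkpoint selection by best validation accuracy (earliest epoch
on ties). The velocity update is `v ← μv + (g + λw)`, `w ← w − ηv`. Data are
reshuffled every epoch from the run seed and the final partial batch is
used; a non-finite loss aborts with a diagnostic rather than continuing. A
learning rate of exactly 0 is permitted (a no-op optimizer, useful for
testing invariances). Momentum 0.9 is the conventional default; the source
recipe names the optimizer but not the coefficient.

## Evaluation statistics

All statistics derive from the k×k confusion matrix (rows true, columns
predicted): per-class precision, recall and F1; unweighted macro averages;
overall accuracy; for binary tasks, sensitivity (recall of the designated
support class), specificity (recall of the other class) and the geometric
mean √(sens·spec); balanced accuracy (macro recall, which equals the
arithmetic mean of sensitivity and specificity in the binary case, and by
AM–GM never falls below the G-mean). Zero denominators (e.g. a class never
predicted) produce 0 with a warning, so degenerate models still yield
reports. Values are kept at full precision on the percent scale; display
rounding is half-up to two decimals.

Accuracy inference reports a 95% Wilson score interval (primary) and the
normal-approximation interval (secondary), plus the exact one-sided binomial
tail P(X ≥ correct | n, baseline). For the reference confusion matrix
(206/15/19/275) these give 90.92–95.24 (Wilson) and 91.25–95.54 (normal);
since the two methods bracket rather than reproduce a single printed
interval, the CI is reported but not treated as a target quantity.

Precision-recall curves sweep all distinct predicted probabilities one
class versus the rest, predicting positive at score ≥ threshold; the sweep
stops at the first threshold achieving full recall, past which recall is
constant and precision only decays.

## Synthetic data generator

The generator emulates weight-normalized pedobarographic images: a
foot-shaped soft mask (union of heel, arch, forefoot and toe ellipses,
~20% of the plate), a heel-to-toe center-of-pressure polyline rendered as a
narrow Gaussian ridge, additive Gaussian sensor noise (σ = 0.02 by
default), and body-weight normalization — every image is rescaled to the
same total load (0.038·size² by default, keeping peaks below intensity 1).
The `osteoarthritis` class places 1–3 compact Gaussian hotspots
(σ ∈ [0.04, 0.06] of the image side, amplitude 0.55–0.75) at distinct
anatomical anchors on a faint base load; the `control` class spreads the
same total mass smoothly over the mask with mild large-scale unevenness.
Class indices are lexicographic, so `control` = 0. Generation is a pure
function of the spec (one seeded generator), and the hotspot ground-truth
masks are available for saliency checks.

What the generator does *not* emulate: temporal gait dynamics, sensor-array
quantization and calibration drift, anatomical variation between subjects,
partial steps, or the colormapped rendering of clinical software (images
are grayscale replicated to three channels). Tests that pass on this data
therefore establish that the implementation is correct and that the
architecture can learn a focal-vs-diffuse contrast — not that it reaches any
particular accuracy on clinical data.

## Scaled-down experiment sizes

Training and saliency experiments in the test suite run a narrow variant —
widths (8, 16, 32, 64) on 96×96 inputs (96 is the smallest multiple of 32
that keeps the final stage at the 3×3 pooling minimum) — with the standard
recipe at batch 16 on 64 synthetic images. This is the problem size at
which the full pipeline (generation → training → evaluation → Grad-CAM) is
comfortable on a single CPU with the numpy engine; the variant reaches 100%
training accuracy within 30 epochs and a clean held-out split, and its
saliency maps concentrate inside the generated hotspots. The full-width
network is exercised for construction, shape tracing, parameter counting
and single forward passes, not for training.

## Grad-CAM

Saliency targets the output of the last TNV2 stage (pre-GAP). Channel
weights are the spatial means of the gradient of the chosen class logit;
the map is the ReLU of the weighted channel sum, bilinearly upsampled to the
input size and min-max normalized to [0, 1]. Using the logit (not the
softmax) makes the map invariant to adding a constant to all class scores.
A constant raw map — e.g. under an all-zero head — yields the documented
degenerate all-zeros heat. Overlays blend a perceptually uniform colormap
(viridis) at α = 0.45.

## Known limitations

- The numpy engine is single-device and eager; it is sized for research and
  testing, not for large-scale training (no data augmentation, no learning
  rate schedules, no mixed precision).
- Batch-norm behavior with batch size 1 in training mode is well-defined but
  statistically weak, as in any framework.
- Specificity and G-mean are defined for binary tasks; multi-class reports
  carry per-class and macro statistics plus balanced accuracy instead.
- The precision-recall sweep enumerates distinct predicted probabilities;
  with heavily saturated softmax outputs many samples share a threshold and
  the curve has few points.
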