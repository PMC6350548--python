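# Methods

## Network model

The segmentation network is an encoder–decoder with dense connectivity.
A dense layer is BN → ReLU → 3×3 same-padding convolution (adding
`growth_rate` feature maps) → dropout; a dense block stacks
`layers_per_block` such layers, each consuming the concatenation of the
block input and all previous layer outputs. The block *output* is the
concatenation of the new feature maps only; on the downsampling path this
output is concatenated with the block input before the transition (and that
concatenation is stored as the skip tensor), while on the upsampling path
only the new feature maps propagate — this prevents linear growth of the
channel count through the decoder.

A transition down is a 1×1 channel-conserving convolution followed by a 3×3
stride-2 convolution (convolution replaces 2×2 pooling to reduce information
loss). A transition up is a single 3×3 stride-2 transposed convolution,
applied only to the preceding dense block's output; its result is
concatenated with the same-resolution skip tensor. The classifier is a 1×1
convolution over the concatenation of the last dense block's input and
output, followed by a per-pixel softmax.

The bottleneck is either:

* **ASPP** (proposed variant): one 1×1 branch plus one 3×3 atrous branch per
  sampling rate (defaults 6, 12, 18), each producing `branch_channels` maps;
  branch outputs are concatenated together with the bottleneck input and
  fused by a final 1×1 convolution. With 4 transitions per path this gives
  47 counted layers.
* a dense block (baseline FC-DenseNet56, 5 transitions, 56 counted layers).

**Layer-counting convention.** The two published totals (47 and 56) are
reproduced simultaneously only if one counts: the initial convolution, every
dense-layer convolution, one unit per transition down (even though ours
contains two learnable convolutions), one transposed convolution per
transition up, the 5 ASPP convolutions (or the 4 bottleneck dense layers),
and the final classifier convolution. `count_layers` implements exactly this
convention; both convolutions inside the transition down remain learnable.

**Choices the architecture description leaves open**, fixed here as
defaults and kept configurable:

* `initial_features` = 48 (the original FC-DenseNet convention);
* ASPP branch width = `layers_per_block × growth_rate` (48 at the default
  configuration), keeping the channel flux comparable to the dense
  bottleneck the module replaces; the fusion 1×1 also emits this many maps,
  so the decoder sees the same width in both variants;
* ASPP atrous branches use 3×3 kernels; no dropout inside ASPP;
* the classifier consumes concat(input, output) of the last dense block.

At the bottleneck of the 512-input configuration the feature maps are 32×32
while rate 18 has an effective kernel of 37: the construction warns (the
branch degenerates toward its central taps) but proceeds, as the rates are
part of the published design.

## Numerical backend

The networks are realized on a compact reverse-mode autodiff backend over
numpy (`mammodense.backend`): im2col-based convolution with stride and
dilation, transposed convolution as zero-stuffing + convolution (3×3,
stride 2, asymmetric padding so the side exactly doubles), batch
normalization with running statistics, inverted dropout, channel
concatenation, and Adam. Gradient correctness is pinned by finite-difference
tests, and the dilated convolution is pinned against standard convolution
with the explicitly zero-inserted kernel for rates 1, 2, 3 and 6.

Weight initialization is He-uniform for convolutions, identity for BN,
zero biases, all seeded; inference BN uses the running statistics
(momentum 0.1). "Same" padding is zero padding of (effective kernel − 1)/2;
a stride-2 convolution on an odd side raises an error rather than guessing
an alignment. Tensors are float32; losses/metrics accumulate in float64.

## Losses

Class frequencies are computed **per image** at loss time by default (the
imbalance is image-dependent); a dataset-wide `ClassFrequencies` can be
passed instead. Numerical floors: predicted probabilities are clamped to
[1e−7, 1] before logs; class frequencies are floored at 1e−4 so tumor-free
images yield finite weights (the frequency-sum invariant is checked with a
matching tolerance). Natural log throughout. Dice loss is the soft variant
with smoothing s = 1 (configurable), computed on class-1 probabilities.
Training backpropagates analytically derived loss gradients with respect to
the logits (fused with the softmax), which avoids the numerical hazards of
differentiating through log of clamped probabilities.

## Metrics

PA is foreground recall TP/(TP+FN), *not* global pixel accuracy — it is
deliberately blind to false positives, which is why DI and IoU are the
primary precision measures. Aggregation over an evaluation set is the
per-image arithmetic mean (a pooled-counts mode exists behind a flag). When
prediction and truth are both empty, DI/PA/IoU are defined as 1 and a
warning is emitted; this never occurs on phantom sets with tumors.

## Phantom generator

Each phantom is: dark background (0.05), half-elliptical breast region
(base intensity 0.45) anchored to the left edge with mildly randomized
axes, three octaves of smoothed Gaussian noise as parenchymal texture
(amplitude `texture_scale`, default 0.06), an optional pectoral wedge
(+0.15) in the top-left corner for MLO-like views, and `n_tumors` lobulated
ellipses — a rotated ellipse whose radius is modulated by two low-order
sinusoidal harmonics (total amplitude ≤ 15% of the radius) — placed fully
inside the breast, with intensity offset `tumor_contrast` (softened at the
boundary by a σ=1 blur; the mask is the exact unsoftened support). Additive
Gaussian pixel noise (`noise_sd`, default 0.02) and clipping to [0, 1]
finish the image.

Tumor bounding boxes are kept inside `tumor_size_range` by construction
(major diameter sampled so that the perturbed minor extent stays above the
minimum) plus a render-and-check retry; the default range maps the clinical
200–800 px interval (at 4096-px image height) proportionally to the canvas,
e.g. (50, 200) at 1024. Default phantoms have < 10% tumor pixels,
reproducing the imbalance that motivates the weighted loss.

Desk-scale test phantoms are 64×64 with tumor diameters 10–20 px — chosen
to preserve the clinical-scale tumor area fraction (a 200–800 px tumor on a
3328×4096 image occupies ~0.2–3.7% of the pixels; 10–20 px on 64² gives
~2–8%) — with contrast 0.25 over noise 0.03 for optimization checks, and
contrast 0.08 for the low-contrast ablation.

Phantoms are test doubles: they reproduce gross intensity structure, class
imbalance and contrast regimes, not mammographic physics (no scatter, no
compression artifacts, no calcifications, no realistic parenchymal
patterns). Passing tests therefore demonstrate that the pipeline learns and
measures correctly under the assumed statistical structure, not clinical
performance.

## Training protocol

Adam with default betas, learning rate 0.001, batch size 1, dropout 0.2,
BN, 100 epochs by default (the small batch is compensated simply by the
long schedule; no gradient accumulation, LR schedule, weight decay, early
stopping or augmentation). The checkpoint with the best validation mean
Dice is kept (final weights when no validation set is supplied); which
checkpoint to report was an open choice, and best-validation is this
package's. Inference binarizes by per-pixel argmax (probability ≥ 0.5) and
resizes the mask back to the source resolution with nearest neighbor.
Training is deterministic for a fixed seed in single-threaded CPU mode.

Desk-scale runs in the test suite use the tiny configuration (growth 4,
2 layers/block, 2 transitions, ASPP rates (2, 4), 16 initial features,
64×64 inputs) with 150–300 optimization steps — sizes at which the full
forward/backward pipeline, dense connectivity and every ASPP branch are
exercised in seconds.

## Classical baseline

"Iterative threshold" is implemented as the ISODATA/Ridler–Calvard fixed
point t ← (mean below t + mean above t)/2 started from the global mean
(tolerance 1e−3, ≤ 100 iterations), the canonical reading of the phrase.
The second threshold — the mean of the first-pass region — is applied to
the whole image, not only within the first-pass region. Small-component
removal uses 8-connectivity with a default minimum area of 0.1% of the
image; both choices were unspecified and are configurable.

## Known limitations

* The numpy backend is CPU-only and unoptimized for full-resolution
  training; the full 47-layer network at 512×512 runs forward in about a
  minute per image, so clinical-scale training would require a GPU backend.
* Pectoral-muscle removal (used upstream of classical comparators on MLO
  views) is not implemented; the published description is under-specified.
* No pretrained weights, comparison deep models, level-set or graph-cut
  baselines.
* The per-image frequency weighting makes the loss scale vary across
  images with different tumor areas; dataset-wide frequencies are available
  when a comparable scale matters.
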