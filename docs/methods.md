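# Methods

## Problem setting

Pressure-injury staging is a 4-way fine-grained image classification
task: the classes share most of their appearance (skin, wound bed,
periwound tissue) and differ in subtle texture, colour and edge
structure. The architecture here counters the usual deep-CNN failure
mode — detail loss in late, semantically strong layers — by fusing the
three deepest feature scales in both directions and letting the network
*learn how much each scale contributes* at every fusion site.

## Architecture

**Backbone contract.** Any trunk that maps an N×3×H×W batch (H, W
divisible by 32, non-empty batch) to three maps {B4, B5, B6} at strides
16/32/64 and reports their channel widths is a valid backbone. Two are
provided: a ResNeXt-50 (32×4d) trunk whose two deepest native stages
carry 1024 and 2048 channels, and a small plain-convolution trunk for
fast experiments. Five-stage trunks end at stride 32, so B6 is
synthesised by an extra stride-2 3×3 convolution on B5 (the RetinaNet
P6 construction); its width defaults to 512 — a free choice, since the
neck's 1×1 projection absorbs any input width. Pre-trained trunk
weights can be loaded from an `.npz` state dict but are never required;
all tests run from seeded random initialisation.

**Fast-normalised fusion.** Each fusion node holds one raw scalar per
input, rectified (ReLU) to guarantee non-negativity, initialised to 1.
With ε = 1e-4 the applied coefficients w_i/(Σw_j + ε) are each in
[0, 1), sum to Σw/(Σw + ε) < 1, and increase strictly in their own raw
weight while decreasing in the others. ε = 0 is accepted for exact
arithmetic (used in tests), in which case the rectified weights must
not all vanish. The arithmetic order at every site is: project (1×1)
→ weight-normalise-sum → smooth (3×3).

**Top-down pathway.** The seed map F6 applies global average *plus*
global max pooling to B6 and a 1×1 projection; taking the pooling
literally makes F6 spatially 1×1, so the level-6 branch carries global
context and its upsampling is a spatial broadcast. This degeneracy is
intentional — the global pooling is explicit in the design — and the
level-6 CBAM and classifier degenerate gracefully on 1×1 maps (the 7×7
spatial convolution uses padding 3).

**Attention.** One CBAM per pyramid level, with independent parameters
(levels see very different statistics; sharing is the other defensible
choice and was rejected for expressiveness). Channel attention pools
globally over space, spatial attention pools across channels —
disambiguating the overloaded avg/max-pool notation the two halves
share. Reduction ratio defaults to 16, the standard CBAM setting.
Both gates are sigmoidal, so refined maps never exceed the input in
element-wise magnitude.

**Bottom-up pathway and heads.** P4 = F″4 (the lowest node has no lower
input — symmetric with F6's special-casing at the top); deeper nodes
fuse F″n with a downsampled P_{n−1} and need no projection since
everything is already 256-wide. Resize-up is nearest-neighbour;
resize-down is adaptive average pooling (global averaging when the
target is 1×1). Each P level is classified by global average pooling →
FC(256) → ReLU → FC(K); the ensembled quantities are raw logits, not
probabilities, and the ensemble's ε is added once to the summed
denominator — deliberately different from the per-node normalisation,
matching the classifier's definition. Predicted label is the argmax,
ties broken toward the lower class index. The training loss is
cross-entropy on the ensembled prediction only; no per-level auxiliary
losses, label smoothing or class weighting.

## Training recipe

AdamW with decoupled weight decay (lr 2e-4, weight decay 1e-4), cosine
annealing lr(t) = η_min + (lr₀ − η_min)(1 + cos(πt/T))/2 stepped per
epoch with T = total epochs and floor 0, batch size 16, 224×224 inputs,
and per-channel normalisation with the corpus statistics
mean = (0.537, 0.424, 0.393), std = (0.523, 0.416, 0.376) (recomputable
for any dataset via `wfpn stats`). Epoch count defaults to 100 and is
configurable; no augmentation beyond resize + normalisation. The best
checkpoint is selected by validation accuracy. Training aborts with
diagnostics on a non-finite loss.

**Stratified split.** The validation share of a class with n_c items is
floor((1 − ratio)·n_c), computed in decimal arithmetic because binary
floating point turns 0.2 × 385 into 76.999… and floors one item short.
At the corpus stage sizes (385, 523, 318, 293) and ratio 0.8 this
yields validation shares (77, 104, 63, 58) and training shares
(308, 419, 255, 235). Note the per-class floors sum to 302/1217, not
the 303/1216 sometimes quoted for this corpus; the flooring rule is the
one consistent with every per-stage pair.

## Numerical engine

No GPU framework is assumed: `wfpn.nn` is a compact reverse-mode
autodiff engine on NumPy — conv2d via im2col + BLAS with a col2im
gradient (grouped, strided, padded), max/adaptive-average pooling,
nearest-neighbour resize, batch normalisation with running statistics,
numerically stable sigmoid/log-softmax/cross-entropy, AdamW and cosine
annealing. All arithmetic is float64; at the model sizes used here a
full ResNeXt-50 forward pass at 224×224 takes under a second on one
CPU core, and the tiny-trunk training runs used in the tests take a few
seconds. Every operation's gradient is verified against central
differences in the test suite. Two details worth knowing: max-pooling
ties share their gradient equally (rather than electing one winner),
and batch-norm running variance uses the unbiased estimator.

## Synthetic data generator

The generator emulates the *task structure* of wound staging, not its
appearance: four classes share one background distribution (jittered
skin tone with smooth multi-octave value noise) and differ only in the
parameters of a central elliptical lesion — a diffuse feathered red
patch (1), a small sharp pale break (2), a dark-cored crater with a
granular ring (3), and a large dark region with a high-contrast rim
(4). A `separability` scalar s interpolates every class parameter
toward the across-class mean: at s = 1 classes are maximally distinct,
at s = 0 all four draw from one distribution and a colour-statistics
classifier scores ≈ 0.25. Defaults: 100 images per class, 224×224,
noise σ = 0.05, s = 1. Generation is fully determined by the seed
(per-image child seeds from one `SeedSequence`), so written trees are
byte-identical across reruns.

What passing tests on this generator do **not** show: robustness to
photographic nuisance (lighting, pose, occlusion, devices), to clinical
ambiguity between adjacent stages, or to the class imbalance and label
noise of real corpora. The generator exists to exercise the
architecture, pipeline and metrics end-to-end, and to provide
controlled difficulty.

## Problem sizes used in the tests

The suite runs the compact trunk on 32–64 px inputs: the overfit sanity
check uses 40 images (10/class, separability 1, 32×32, lr 5e-3 — an
overfitting run wants a hotter rate than the production default) and
reaches training accuracy 1.0 within 30 epochs; the end-to-end
reproducibility check trains 3 epochs on 32 images and compares two
seed-identical runs for exact equality. The full-width model is
exercised at 224×224 in forward mode to verify the 256-channel contract
of all six fused maps.

## Degenerate inputs and edge policies

* Metric cells with zero denominators (class never predicted, empty
  recall base) are defined as 0 and logged; AUC for a class absent from
  the truth is undefined and excluded from the macro mean with a
  warning.
* Row-normalised confusion matrices leave all-zero rows at zero.
* ROC curves collapse tied scores onto single points; AUC is
  trapezoidal and equals the Mann–Whitney U statistic on the binary
  problem.
* Fusion rejects shape or arity mismatches; the backbone rejects wrong
  channel counts, spatial sizes not divisible by 32, and empty batches.

## Known limitations

* Validation-set accuracies on real clinical corpora are out of reach
  here by construction: they require the multi-center images and
  ImageNet pre-training. This package verifies the architecture's
  contracts and arithmetic, and its trainability on controlled data.
* Only the two bundled trunks are first-class; other backbones plug in
  through the adapter contract but ship without weights.
* The engine is CPU-only and eager; it favours correctness and
  inspectability over speed, and large-batch 224×224 *training* of the
  full trunk is correspondingly slow.
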