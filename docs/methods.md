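# Methods

## The architecture as data

The network is represented as an ordered DAG of layer records
(`graph.ArchitectureGraph`) rather than framework layer objects. Insertion
order is topological by construction (a layer may only reference already
defined inputs), which makes shape inference, parameter accounting and the
model summary single linear passes of integer arithmetic. The accounting
conventions are fixed by the published per-layer parameter counts:

- convolutions carry a bias: `filters × (kh·kw·c_in + 1)` parameters
  (e.g. the stem: 32 × (3·3·3 + 1) = 896);
- batch normalisation holds 2C trainable (scale, shift) and 2C
  non-trainable (running mean, running variance) values, which is what makes
  the non-trainable total exactly twice the 3,872 feature maps (7,744);
- the dense head has `classes × (in + 1)` parameters.

Shapes are channels-last. Stride-1 'same' convolution preserves spatial
dims; 2×2/stride-2 'same' pooling maps d → ⌈d/2⌉ (ceiling only matters for
non-default input sizes — every pooled dimension is even in the default
configuration).

### Width parameterisation

`build_hierbanet(input_shape, num_classes, num_blocks, base_width)` exposes
the block count (1–3) and a `base_width` for desk-scale variants. All
channel widths are tied to the stem width by the ratios of the default
architecture: diversified branches and the low-level module use 2× the base
width, the two mid refinement convs 8×, the high-level output 16×, and the
trunk conv after each block 18× (= 16× + 2× of the concatenation). With
`base_width=32` this reproduces the published table exactly; with
`base_width=4` it yields a coherent ~90k-parameter miniature used
throughout the tests.

Each block is followed by its own trunk convolution and pool, so the
ablation variants have 10 / 19 / 28 convolutional layers for 1 / 2 / 3
blocks (the trunk conv count is `num_blocks + 1`).

The summary's growth-rate column is the running sum of convolutional output
channels in topological order, with the diversified branches serialized
1×1, 3×3, 5×5, 7×7 and the high-level module before the low-level module
within a block. An embedded golden CSV of the published summary backs
`summary --check`, which exits non-zero with a per-row diff on any mismatch.

## Numerical semantics

`ops.py` defines each layer's computation on single (H, W, C) float64
tensors: cross-correlation with zero 'same' padding (the deep-learning
convention; kernels are not flipped), batch normalisation with stabiliser
c = 0.001, LeakyReLU with negative slope 0.001 (as specified, not the more
common 0.01/0.3), 'same' max pooling, global average pooling, softmax head,
and inverted dropout (identity at inference; kept units scaled by
1/(1−rate) during training so the expectation is preserved). Predicted
class is the argmax of the probabilities; exact ties break toward the
lowest class index.

`nn.py` is the batched engine used for training: the same operators on
(N, H, W, C) batches with analytic backward passes. Convolution is computed
as kh·kw shifted matrix products, max-pool backward routes gradients through
the per-window argmax (first maximum on exact ties), and the batchnorm
backward differentiates through the batch statistics. The softmax and
cross-entropy gradients are fused. A batch-of-one inference pass agrees
bitwise with the reference path; gradients were validated against central
finite differences with an eps-convergence study (the loss is only
piecewise smooth, so the stencil must be narrower than the smallest
max-pool window gap).

### Batch-normalisation statistics

Training uses per-batch statistics (biased variance, 1/m). Inference uses
running averages with momentum 0.99, stored as **bias-corrected**
exponential moving averages: the raw EMA (initialised at zero) is divided
by 1 − 0.99^t after t updates, exactly as Adam corrects its moment
estimates. Without the correction a freshly initialised network needs on
the order of several hundred updates before the running statistics stop
being dominated by their initial values; at desk scale (tens of parameter
updates per fold) the inference path would then be useless even when the
training path has converged. The corrected estimate equals the plain EMA in
the long-run limit and equals the observed batch statistics exactly after
the first update.

## Data pipeline

Images are indexed from a `Train/Val/Test/<class>/` tree; class ids follow
lexicographic class-name order and files are sorted, so indexing is fully
deterministic. Preprocessing is bilinear resize to the network input size
and scaling by 1/255.

Augmentation (training-time only, applied online per batch) draws uniformly:
rotation ± 45°, zoom factor 1 ± 0.25, shear coefficient ± 0.25 ("slant" is
interpreted as a shear coefficient; no unit is standard), width/height
shifts ± 30%, independent 50% horizontal/vertical flips, and a
multiplicative brightness factor in [0.2, 0.9] (interpreted as an intensity
multiplier). Transform order is flip → rotate → shear → zoom → shift →
brightness; the geometric part is composed into a single bilinear affine
resampling with nearest-edge fill, and outputs are clipped to [0, 1].
Augmentation is off by default in the desk-scale harness (the tiny synthetic
classes are deliberately orientation-coded, and the published hyper-parameter
set does not couple augmentation to the training configuration); it is
enabled with `train --augment` or programmatically via an
`AugmentationConfig`.

Stratified k-fold construction (default k = 10, over the train+val pool)
delegates to scikit-learn's `StratifiedKFold` with shuffling under the run
seed; per-fold class counts are within one sample of n_c/k.

## Training protocol

Glorot-uniform initialisation (bound √(6/(fan_in+fan_out)), kernel fans for
convolutions), zero biases, identity batchnorm. Adam with lr 0.001,
β₁ = 0.9, β₂ = 0.999, ε = 1e−7; batch size 32; one epoch visits every
training sample exactly once in shuffled mini-batches. Labels are one-hot;
the loss is categorical cross-entropy.

Early stopping monitors validation accuracy with patience 5: training halts
after five consecutive epochs without a new best, and the best epoch's
weights (ties broken by lower validation loss, then the earlier epoch) are
restored, including their running batchnorm statistics. The k folds are
trained in order and each fold is seeded with the previous fold's best
weights (weight carryover); the optimiser state is reset per fold. The
final fold's best weights are the model that is evaluated.

## Evaluation

The K×K confusion matrix (rows true, columns predicted), per-class
one-vs-rest 2×2 matrices, and accuracy / precision / recall / F1 under
**macro** (unweighted per-class) averaging. Macro averaging is the
convention that reproduces the published metric table from the published
misclassification counts to four decimals, which fixes the choice; classes
with no predicted (or actual) members contribute 0 to the affected metric.
ROC curves use a full threshold sweep with trapezoidal AUC; PR curves use
step-wise interpolation (the PR-AUC equals scikit-learn's average
precision). Both are computed one-vs-rest per class from the softmax
scores.

## Synthetic data

The generator renders three procedurally distinct plant-texture classes on
a brown-green backdrop, mirroring the morphological axis that separates a
cereal crop from its weeds: `sorghum` — thick full-height stalks with
bright midribs, one per vertical band; `grass` — many thin bright blades
fanning upward, stratified across the width; `broadleaf` — large dark
elliptical lobes on a jittered 3×3 grid. Stratified placement keeps
foreground coverage consistent within a class, and per-class reflectance
bands differ modestly, as leaf reflectance does in the field. Additive
Gaussian pixel noise (default sd 10 of 255) roughens every image. Files are
JPGs in the standard per-class Train/Val/Test layout with a 7:2:1 split,
byte-identical under a fixed seed.

`separability_check` guards learnability before the network is blamed: a
nearest-centroid classifier on luminance features area-averaged to 8×8
must reach balanced accuracy ≥ 0.8 on the test split (features are computed
from a 32-px render and block-averaged, because bilinear resampling straight
to 8 px point-samples and aliases). Against permuted labels the same
baseline falls to chance.

What passing the desk-scale suite shows — and does not show: the tiny
variant (32×32, base width 4) trained 2-fold on 50 images/class reliably
exceeds the permutation-null band (observed test accuracy ≈ 0.93 at the
default seeds), demonstrating that graph construction, the numeric kernels,
backprop, the fold protocol and evaluation compose correctly. The synthetic
classes are far cleaner than field imagery (no occlusion, soil variation,
scale changes or illumination extremes), so these numbers say nothing about
accuracy on real crop–weed datasets, and full-scale training runs are out
of scope here.

## Numerical and design choices

- All reference and training computation is float64; determinism is exact
  under fixed seeds (inference is bitwise reproducible).
- 'Same' padding puts the extra pixel after (bottom/right) for even kernels
  or strides; all published kernels are odd and stride 1, where padding is
  symmetric.
- Max-pool padding uses −∞ so padded cells can never win a window.
- Softmax subtracts the row maximum before exponentiation; probabilities
  are clipped at 1e−12 inside the cross-entropy only.
- Checkpoints are HDF5, one group per layer, with the architecture
  hyper-parameters stored as root attributes so a checkpoint is
  self-describing; loading validates every array shape against the rebuilt
  graph and names the first offending layer.
- Known limitations: no GPU or threaded backend (the 224×224 full-width
  model is executable but slow to train in pure NumPy); non-square kernels
  and strides other than 1 (conv) / 2 (pool) are outside the supported
  envelope; EXIF orientation is not handled.
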