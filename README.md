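# hierbanet

A verifiable re-implementation of **HierbaNetV1**, a two-block multi-scale
convolutional feature-extraction architecture for crop–weed image
classification, together with its preprocessing, training protocol and
evaluation — in plain NumPy, with no deep-learning framework required.

The package is aimed at researchers who want to audit, probe or re-train the
architecture at desk scale: the network is represented as an explicit layer
graph whose shapes and parameter counts are exact integer arithmetic, every
layer's numerics are defined by small reference kernels, and a synthetic
three-class plant-texture generator lets the whole pipeline run in minutes on
a laptop with no dataset download.

## The architecture

An input image ($224 \times 224 \times 3$, values scaled by $1/255$) passes
through a stem convolution and then two *feature-integration blocks*. Each
block applies two modules to the same input:

- **High-level module** — four parallel *diversified* kernels
  ($1{\times}1$, $3{\times}3$, $5{\times}5$, $7{\times}7$, 64 filters each)
  whose outputs are concatenated (256 channels) and refined by three
  $3{\times}3$ stages (256, 256, 512 filters), then max-pooled. The four
  kernel sizes target regions of interest of different spatial extent, so a
  seedling and a full leaf canopy are captured by the same block.
- **Low-level module** — a single $3{\times}3$ convolution (64 filters) and a
  pool, propagating basic structure (edges, colour) forward unchanged in
  character.

The block output is the channel concatenation
$F = \{F_{HL} + F_{LL}\}$ (512 + 64 = 576 channels), i.e. 1,280 high-level
and 64 low-level feature maps are generated per block. Every convolution is
followed by batch normalisation
$s_{bn} = p_1 (s_c - b_m)/\sqrt{b_v^2 + c} + p_2$ with $c = 0.001$ and a
LeakyReLU with negative slope 0.001. The head is global average pooling
(576 features), dropout 0.2 and a softmax dense layer. In the default
configuration the graph has 72 layers, 19 of them convolutional, producing
3,872 feature maps and 14,331,331 parameters (14,323,587 trainable).

Training follows the published protocol: Glorot-uniform initialisation,
Adam (lr $10^{-3}$, $\epsilon = 10^{-7}$), batch size 32, stratified
10-fold cross-validation with early stopping on validation accuracy
(patience 5) and carryover of each fold's best weights into the next fold.

## Worked example

Verify the architecture against the embedded golden summary, then run the
full pipeline on the synthetic dataset at desk scale (a 32×32 variant with
base width 4; about half a minute of CPU):

```bash
hierbanet summary --check
hierbanet synth --out demo/data --n-per-class 50 --size 32 --seed 7
hierbanet train --data demo/data --out demo/run \
    --input-size 32 --base-width 4 --folds 2 --epochs 20 --seed 3
hierbanet evaluate --data demo/data --weights demo/run/weights.h5 --out demo/run
```

`summary` prints one row per convolutional layer (name, output shape,
parameters, kernel, filters, cumulative feature-map growth) and the totals:

```
Total params: 14,331,331
Trainable params: 14,323,587
Non-trainable params: 7,744
Total feature maps generated: 3,872
```

`--check` exits non-zero with a per-row diff if any entry deviates from the
published table. The train / evaluate steps print:

```
trained 2 folds; best val accuracy per fold: 0.926, 0.985
Confusion matrix (rows = true, cols = predicted):
           broadleaf      grass    sorghum
broadleaf          5          0          0
    grass          0          5          0
  sorghum          0          1          4

Accuracy         0.9333
Macro precision  0.9444
Macro recall     0.9333
Macro F1         0.9327
```

so the tiny variant learns the three synthetic texture classes (stalks,
thin blades, broad lobes) well above the chance level of 1/3. Early stopping
fired in both folds, and fold 2 resumed from fold 1's best weights.
`hierbanet featuremaps` exports a PNG grid of intermediate activations per
convolutional layer and `hierbanet predict` classifies a single image.

As a library:

```python
from hierbanet import build_hierbanet, count_parameters, summarize

graph = build_hierbanet()            # 224x224x3, 3 classes, 2 blocks
print(count_parameters(graph).total) # 14331331
print(summarize(graph)[-1])          # Base_Conv3 row, growth 3872
```

## Layout

- `src/hierbanet/graph.py` — architecture graph, shape inference, parameter
  accounting, model summary, text/CSV serialization
- `src/hierbanet/ops.py` — single-image reference kernels (float64)
- `src/hierbanet/nn.py` — batched forward/backward engine and Adam
- `src/hierbanet/data.py` — dataset indexing, preprocessing, augmentation,
  stratified k-fold
- `src/hierbanet/training.py` — fold loop, early stopping, weight carryover
- `src/hierbanet/evaluation.py` — confusion matrices, macro metrics, ROC/PR
- `src/hierbanet/synth.py` — synthetic plant-texture dataset generator
- `src/hierbanet/cli.py` — the `hierbanet` command
- `docs/methods.md` — modelling and implementation notes
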