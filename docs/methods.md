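# Methods

## Problem and model

Skin-lesion classifiers that see only the image ignore exactly the
information a clinician uses alongside the dermatoscope: the patient's
sex, age band, the anatomical region of the lesion, whether it bleeds,
and so on. `metafuse` implements three ways of injecting that categorical
metadata into a convolutional classifier, all operating on the backbone's
pre-pooling feature map `X_img ∈ R^{k_img × h × w}` and a one-hot metadata
vector `x_meta ∈ {0,1}^{d_meta}`:

- **MetaNet** (multiplicative channel reweighting).  A two-layer network
  `s = σ(W₂ᵀ relu(W₁ᵀ x_meta + b₁) + b₂) ∈ (0,1)^{k_img}` produces one
  scale per feature channel; the output is `s ⊙ X_img` with `s`
  broadcast over the spatial grid.  Metadata can silence or pass each
  channel but never change its sign or amplify it.

- **MetaBlock** (gated modulation).  Two affine maps of the metadata,
  `f_b(x) = W_fᵀ x + w_{0f}` and `g_b(x) = W_gᵀ x + w_{0g}`, both in
  `R^{k_img}`, drive an LSTM-like gate pair:

      X_out = σ( tanh( f_b(x_meta) ⊙ X_img ) + g_b(x_meta) )

  where `⊙` scales each channel by its modifier and broadcasts
  spatially.  The tanh gate maps every feature into (−1, 1), the sigmoid
  gate into (0, 1); the output has exactly the input's shape.  The
  expression is implemented literally as the composition of the two
  gates; there is no second multiplication by `X_img` after the sigmoid
  (the gated map itself is the block output, consistent with the output
  shape matching the input feature array).

- **MD-Net** (combination).  Both blocks run on the same feature map;
  each output is globally average-pooled to a `k_img` vector, projected
  by its own affine map to a common dimension `d_fuse`, and the two
  streams are concatenated into the classifier input (summation after
  projection is available as `mode="sum"`; concatenation is the default
  so the classifier sees both streams unmixed).

Baselines: **Concatenation** (pooled image features with `x_meta`
appended) and **None** (pooled image features alone).  A dropout layer on
the fused vector feeds a single affine softmax classifier.

Modifier granularity is per-channel: the weight shapes
`W_f, W_g ∈ R^{d_meta × k_img}` force one modifier per feature map, which
is then shared across the spatial grid.  `k_img` is read as the number of
feature maps produced by the backbone's last convolutional stage.

## Metadata encoding

Each categorical field expands to a block of bits with exactly one set
(`N` states → `N`-bit register).  Field and category order default to
lexicographic so the schema is a pure function of the observed data;
explicit orders can be supplied (the canonical sex example,
male → (1,0) / female → (0,1), needs the explicit `["male","female"]`
order).  A field missing from a record encodes as an all-zero block —
the least informative code that keeps `d_meta` fixed.  Continuous age is
binned into configurable bands (`bin_age`) before encoding; no learned
embeddings and no imputation.

## Backbones

The fusion blocks need only the extractor contract: images
`(n, 3, H, W)` → features `(n, k_img, h, w)` with a declared `k_img`.
Dense connectivity is the primitive: layer `ℓ` of a dense block consumes
the channel-concatenation of the block input and all earlier layers'
outputs and adds `growth` channels, so output channels =
`in + L·growth`.  Two extractors are built on it:

- `tiny-dense-test` — strided 3×3 stem (8 channels), 2×2 average pool,
  one dense block (growth 4, 2 layers) → `k_img = 16` on an `H/4 × W/4`
  grid.  All tests and the synthetic benchmark use it; nothing is ever
  downloaded.
- `densenet169/121/201` — the generic multi-block dense architecture at
  the standard configurations (bottleneck layers, channel-halving
  transitions); the 169-layer layout yields `k_img = 1664` by
  construction.  These exist to honour the weight-loading contract
  (`load_pretrained(name, weights_path)`); training them at photographic
  scale is out of scope, and no batch normalization is included since
  the random-initialized variants are used only as structural stand-ins.

Fine-tuning unfreezes everything by default; the fusion blocks attach to
the pre-pooling map, never to a pooled vector.

## Training protocol

Multiclass cross-entropy; batch size 30; epoch cap 150; learning rate
halved after 10 validation epochs without improvement and training
stopped after 15 (validation metric = balanced accuracy, the primary
index throughout); best-validation parameters restored at the end; 3:1
train:test split, stratified and seeded, with a further 1/5 of the
training portion held out for validation.  Training images are augmented
with horizontal/vertical flips and bounded brightness, contrast and
saturation jitter (default magnitude ±0.2; augmentation never touches
validation or test data).  The optimizer is Adam at initial rate 1e-3
(plain SGD with momentum is available by config); the choice and rate are
recorded in every checkpoint manifest.  Dropout (rate 0.5) sits on the
fused vector before the classifier.  Class imbalance is handled only by
reporting balanced accuracy; an optional inverse-frequency loss-weight
flag exists and is off by default.

All tensor work runs on a small reverse-mode autodiff engine over
float64 numpy arrays (`metafuse.nn`): convolution via im2col, analytic
gradients checked against central differences in the test suite.  With a
fixed seed and a fixed thread count the whole fit is reproducible; the
suite asserts identical histories across repeated runs.

## Metrics

For `C` classes every rate is computed one-vs-rest and macro-averaged:
sensitivity `TP/(TP+FN)`, specificity `TN/(FP+TN)`, and

    BACC = (sensitivity + specificity) / 2.

This extension keeps the binary identity `BACC ≡ (sens+spec)/2` exact and
makes BACC invariant to per-class duplication of samples.  Because the
binary formula does not pin down the multiclass reading, the mean-recall
variant is also computed and reported as `bacc_recall`; `bacc` always
refers to the (sens+spec)/2 form.  AUC is macro one-vs-rest ROC-AUC
(rank formulation, ties 0.5), delegated per class to scikit-learn and
cross-checked in the tests against an explicit Mann-Whitney count.
Classes with no positives (or no negatives) are excluded from the
affected average with a warning rather than poisoning it with 0/0.

## Synthetic benchmark

The generator emulates the structure of a clinical lesion collection —
an image folder plus a CSV of categorical metadata — at desk scale
(32×32 RGB, default n = 2000, C = 4).  Class `c`'s template is a field of
oriented stripes (orientation `c·180°/C`, random per-sample phase) in a
class-specific hue, so texture and color are the discriminative axes; the
default metadata is a binary field (`sex`) plus an uninformative 4-way
field (`region`).  Confounding is a *permutation of the class→template
assignment conditioned on the binary field*: with probability `λ`
(`meta_effect`) the rendered template is `π_m(c) = (c+m) mod C`, with
probability `1−λ` it is `c`.  Gaussian pixel noise (sd 0.05 on a [0,1]
scale, small against the template contrast) and quantization to 8-bit
PNG complete the image model.

Because the confounding is a finite permutation, both Bayes-optimal
balanced accuracies are computable by enumerating the `(c, m, t)` table
(`bayes_rates`; posterior ties averaged; a Monte-Carlo estimator over
the same table is provided as a check).  At `λ=1, C=4` the image-only
optimum is `(1/2 + 5/6)/2 = 2/3` while image+metadata reaches 1.0; at
`λ=1, C=2` the image is worthless (0.5 vs 1.0); at `λ=0` both rates are
1.0.  For `λ ≤ 1/2` the image-only rule already picks the majority
template, so the metadata gap is zero below that threshold and grows
linearly above it — the benchmark's dial is therefore operated at the
endpoints `λ ∈ {0, 1}`.

What the benchmark does *not* model: photographic lesion appearance,
class imbalance, label noise, metadata missingness correlated with
outcome, and resolution above 32×32.  Passing the benchmark shows that a
fusion block can exploit a genuine image–metadata interaction that a
linear concatenation cannot fully express; it says nothing about
absolute performance on clinical data.

## The metadata-benefit experiment

The central computation (`metafuse.experiments.metadata_benefit`, also
run by `scripts/acceptance.py`): at `λ=1`, with three seeds (dataset,
split, initialization and batch order all re-drawn per seed), the MD-Net
assembly on the tiny backbone is trained alongside the `none` and
`concat` baselines and scored by test BACC on the held-out quarter
(n = 2000 total per seed).  Expected behaviour: the image-only model
converges to its 2/3 ceiling; the concatenation baseline, whose
classifier is linear in `[pooled features, x_meta]`, cannot represent
the permutation switch and lands near the same ceiling; MD-Net, whose
gates give it multiplicative image–metadata interactions, approaches
1.0.  At `λ=0` all variants solve the hue/orientation task and the
fusion advantage collapses to ~0.  Problem sizes (n = 2000, 32×32,
`k_img = 16`, three seeds) keep a full run in the minutes range on one
CPU core while leaving the effect unmistakably larger than seed noise.

## Numerical choices and edge cases

- Float64 throughout; the vectorized blocks match quadruple-nested
  scalar loops to better than 1e-5 relative error.
- Parameter initialization: uniform `±1/√fan_in`, from a seeded
  generator; every stochastic component (init, shuffling, augmentation,
  dropout) draws from its own stream derived from the run seed.
- Strict improvement (`>`) defines "validation improved" for both the
  plateau scheduler and early stopping; the plateau counter restarts
  after each halving so one plateau triggers exactly one halving.
- Degenerate inputs error loudly: empty record lists, unknown
  categories (named with field and value), channel mismatches, empty
  test sets, non-finite losses (abort with epoch and learning rate).
- `tanh`/`sigmoid` outputs are strictly inside their open ranges up to
  float64 saturation (|argument| ≳ 19 and ≳ 37 respectively), which the
  moderate feature scales of normalized images never approach.
- MetaNet's hidden width defaults to `d_meta`; MD-Net's `d_fuse`
  defaults to `⌈k_img/2⌉` ("reduce then re-expand" around the pooled
  dimension).  Both are config-exposed; defaults were fixed once for the
  benchmark conditions.

## Known limitations

- The engine is CPU/NumPy; it is sized for desk-scale experiments, not
  ImageNet-scale fine-tuning.
- No batch normalization, so the large dense configurations are
  structural/contract implementations rather than trainable replicas.
- The mean-recall vs (sens+spec)/2 ambiguity of multiclass balanced
  accuracy is resolved by reporting both (see Metrics).
- Bayes rates assume templates are identifiable under the configured
  noise; at noise levels comparable to template contrast the analytic
  rates become upper bounds (the Monte-Carlo variant inherits the same
  assumption because it enumerates the categorical table, not pixels).
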