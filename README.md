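# metafuse

Metadata-conditioned fusion blocks for convolutional skin-lesion
classification: **MetaNet** channel reweighting, **MetaBlock**
tanh/sigmoid gating, and their **MD-Net** combination, together with
one-hot clinical-metadata encoding, dense convolutional feature
extraction, a balanced-accuracy training protocol, and a synthetic
image+metadata benchmark on which the value of fusion is directly
measurable.

## Who this is for

Researchers studying how per-patient categorical metadata (sex, age
band, anatomical region, boolean symptoms, ...) should be injected into
a CNN that classifies lesion images.  Concatenating pooled image
features with a metadata vector gives a classifier only *additive*
access to the metadata; the fusion blocks here give it *multiplicative*
access — metadata gates and reweights the image features themselves —
which matters precisely when the same visual appearance means different
things for different patients.

## The model

Given a backbone feature map `X_img ∈ R^{k_img×h×w}` and a one-hot
metadata vector `x_meta ∈ {0,1}^{d_meta}`:

- **MetaNet**: `s = σ(W₂ᵀ relu(W₁ᵀ x_meta + b₁) + b₂)`, output
  `s ⊙ X_img` — one sigmoid scale per feature channel.
- **MetaBlock**: with affine modifiers `f_b(x) = W_fᵀx + w_0f` and
  `g_b(x) = W_gᵀx + w_0g`,

      X_out = σ( tanh( f_b(x_meta) ⊙ X_img ) + g_b(x_meta) )

  (channel-wise scaling, spatial broadcast; output shape = input shape).
- **MD-Net**: both block outputs are globally average-pooled, projected
  to a common dimension `d_fuse`, and concatenated before the softmax
  classifier.

Evaluation uses macro one-vs-rest sensitivity and specificity and their
mean, the balanced accuracy `BACC = (Sens + Spec)/2`, as the primary
index, plus accuracy and macro ROC-AUC.  Everything runs on a small
float64 NumPy autodiff engine included in the package; no GPU framework
is required.

## Worked example

Train MD-Net against the image-only baseline on the synthetic benchmark
with fully confounding metadata (`meta_effect=1`: the same stripe/hue
pattern maps to different diagnoses depending on a binary metadata
field, so an image-only classifier is information-limited at BACC 2/3
while image+metadata can reach 1.0):

```python
import numpy as np
from metafuse import (MetaFusionClassifier, SynthConfig, TrainConfig,
                      bayes_rates, generate_dataset, split_dataset)

cfg = SynthConfig(n_samples=2000, n_classes=4, meta_effect=1.0, seed=0)
print(bayes_rates(cfg))
train, test = split_dataset(generate_dataset(cfg), ratio="3:1", seed=0)

def arrays(samples):
    return (np.stack([s.image for s in samples]).transpose(0, 3, 1, 2) / 255.0,
            [s.metadata for s in samples], [s.label for s in samples])

for fusion in ("mdnet", "none"):
    model = MetaFusionClassifier(*arrays(train), fusion=fusion,
                                 config=TrainConfig(seed=0))
    results = model.fit()
    report = results.evaluate(*arrays(test))
    print(fusion, f"test BACC = {report.bacc:.3f}")
```

Output (one CPU, about a minute):

```
(0.6666666666666667, 1.0)
mdnet test BACC = 1.000
none test BACC = 0.671
```

The first line is the analytic Bayes limit with and without metadata:
an image-only classifier cannot exceed BACC 2/3 on this task.  The
trained image-only model converges to that ceiling (0.671), while
MD-Net, whose gates can express the image–metadata interaction, recovers
essentially all of the metadata's value.  `results.summary()` prints the
assembly, parameter count, best epoch and best validation BACC.

A command-line interface wraps the same library:

```bash
metafuse synth --out ds --seed 1 --n 2000
metafuse train --config cfg.yaml      # data dir, fusion variant, protocol settings
metafuse eval  --checkpoint run/checkpoint.npz --data ds
```

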