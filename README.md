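# epunet

Interpretable-by-design CNN ensembles over opponent perceptual feature maps,
with per-feature similarity scores, perceptual relevance maps, and
faithfulness metrics.

## The problem

Post-hoc saliency methods explain a black-box classifier after the fact, and
their explanations need not be faithful to what the model computed. This
package takes the opposite route, aimed at image-classification settings —
biomedical imaging in particular — where the *reason* for a prediction
matters as much as the prediction: the classifier is built as a
**generalized additive model** whose terms are CNNs, so the explanation is
read off the model's own decision variables.

An input image is decomposed into N perceptual feature maps (PFMs) —
humanly interpretable opponent channels: *light–dark* (a smoothed wavelet
approximation of CIE-Lab lightness), *coarse–fine* (the finest wavelet
detail band, an edge/texture map), *blue–yellow* (Lab b) and *green–red*
(Lab a). One independent CNN sub-network per map emits a univariate
**Relative Similarity Score** (RSS) in [−1, 1], and the prediction is

    p = σ( β + Σᵢ RSSᵢ )

so `logit(p) − β` *equals* the sum of the per-feature scores — additivity is
a structural contract, not an approximation. Alongside each prediction the
model produces the RSS bar-chart and one **Perceptual Relevance Map** (PRM)
per feature: entropy-selected mid-layer feature maps, averaged and refined
by maximum-entropy thresholding, locating the image regions behind each
score. Two metrics quantify interpretation quality: **interpretability
accuracy** (mean Jaccard agreement between RSS signs and the class label)
and **ROAD** (confidence change when the least- vs most-salient pixels are
removed and imputed from their retained neighbors).

Everything runs on NumPy/SciPy — the CNN layer stack, including backprop, is
implemented in `epunet.nn` and verified against finite differences — so the
package has no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from epunet import (SynthConfig, TrainConfig, build_epu, explain,
                    extract_pfms, extract_stacks, generate, train)

SIZE = (16, 16)
ds = generate(SynthConfig(n_per_class=80, image_size=SIZE, seed=5))
stacks = extract_stacks(ds.images)
model = build_epu("base_i", input_size=SIZE, seed=0)
train(model, stacks, ds.labels, TrainConfig(epochs=6, seed=0))

held_out = generate(SynthConfig(n_per_class=1, image_size=SIZE, seed=404))
result = explain(model, extract_pfms(held_out.images[1]))
print(result.predicted_class, result.rss.as_dict())
```

Running `python examples/03_explain_prediction.py` (this code with
printing) gives:

```
predicted class: 1 (p = 0.826; 1 = apple-like)
relative similarity scores (negative -> banana-like, positive -> apple-like):
  light_dark   +0.313  +######
  coarse_fine  -0.668  -#############
  blue_yellow  +0.917  +##################
  green_red    +1.000  +####################

additivity: logit(p) = +1.5554 = bias -0.0066 + sum(RSS) +1.5620
PRM[light_dark]: 128 salient pixels (threshold 0.463 at conv layer 5)
...
```

The image is classified apple-like because both color axes vote strongly
for it (red hue: green_red +1.00; non-yellow: blue_yellow +0.92) and
brightness mildly agrees, while the texture sub-network alone leans
banana-like (−0.67) — and the logit of the prediction is exactly the
intercept plus the sum of those four votes. The PRM lines report how many
pixels each sub-network's relevance map marks as salient.

The other scripts in `examples/` walk through PFM extraction
(`01_extract_pfms.py`), training and evaluation (`02_train_and_evaluate.py`)
and the two interpretability metrics (`04_interpretability_metrics.py`).

A thin CLI wraps the same library calls for shell use:

```bash
epunet train --config run.yaml --run-dir runs/demo
epunet explain --checkpoint runs/demo/model.npz --input image.png
epunet evaluate --checkpoint runs/demo/model.npz --dataset data_root/
```

with YAML configs covering the pfm/model/train/synth/metrics sections; see
`tests/test_cli.py` for a minimal config.

## Synthetic benchmark

`epunet.synth` generates a two-class fruit-like benchmark (yellow elongated
crescents vs red/green near-circles on varied backgrounds) with per-channel
`cue_strengths` controlling how much each perceptual axis separates the
classes, exact object masks, and full seed determinism. Setting a strength
to zero makes that channel's class-conditional distributions identical by
construction, which is what makes the interpretation-faithfulness tests
possible without any external data. See `docs/methods.md` for the model,
parameter and design details.

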