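"""Explain a single prediction: RSS bar-chart values and relevance maps.

Trains a small ensemble, then explains one held-out image. Each Relative
Similarity Score (RSS) in [-1, 1] is one sub-network's vote: negative pulls
toward class 0 (banana-like), positive toward class 1 (apple-like), and the
logit of the prediction is exactly the intercept plus their sum. Each
Perceptual Relevance Map (PRM) marks the image regions driving that vote.
"""

import numpy as np

from epunet import (
    SynthConfig,
    TrainConfig,
    build_epu,
    explain,
    extract_pfms,
    extract_stacks,
    generate,
    train,
)

SIZE = (16, 16)

ds = generate(SynthConfig(n_per_class=80, image_size=SIZE, seed=5))
stacks = extract_stacks(ds.images)
model = build_epu("base_i", input_size=SIZE, seed=0)
train(model, stacks, ds.labels, TrainConfig(epochs=6, seed=0))

held_out = generate(SynthConfig(n_per_class=1, image_size=SIZE, seed=404))
stack = extract_pfms(held_out.images[1])  # an apple-like image
result = explain(model, stack)

print(f"predicted class: {result.predicted_class} "
      f"(p = {result.prediction:.3f}; 1 = apple-like)")
print("relative similarity scores (negative -> banana-like, positive -> apple-like):")
for name, v in result.rss.as_dict().items():
    bar = "#" * int(round(abs(v) * 20))
    side = "+" if v >= 0 else "-"
    print(f"  {name:12s} {v:+.3f}  {side}{bar}")
logit = np.log(result.prediction / (1 - result.prediction))
print(f"\nadditivity: logit(p) = {logit:+.4f} = bias {float(model.bias[0]):+.4f}"
      f" + sum(RSS) {result.rss.values.sum():+.4f}")
for prm in result.prms:
    print(f"PRM[{prm.pfm_name}]: {prm.mask.sum()} salient pixels "
          f"(threshold {prm.threshold:.3f} at conv layer {prm.source_layer})")
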