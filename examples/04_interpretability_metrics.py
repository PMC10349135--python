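"""Quantify interpretation quality: interpretability accuracy and ROAD.

On a benchmark where every perceptual cue separates the classes, a faithful
explanation should have all RSS signs matching the class label
(interpretability accuracy near 100%), and removing the pixels a PRM marks
as salient should reduce the model's confidence more than removing the
least-salient ones (positive ROAD score).
"""

import numpy as np

from epunet import (
    SynthConfig,
    TrainConfig,
    build_epu,
    explain,
    extract_stacks,
    generate,
    interp_ground_truth,
    interp_predicted,
    interpretability_accuracy,
    road_score_explanation,
    train,
)

SIZE = (16, 16)

ds = generate(SynthConfig(n_per_class=80, image_size=SIZE, seed=5))
stacks = extract_stacks(ds.images)
model = build_epu("base_i", input_size=SIZE, seed=0)
train(model, stacks, ds.labels, TrainConfig(epochs=6, seed=0))

test = generate(SynthConfig(n_per_class=20, image_size=SIZE, seed=6))
test_stacks = extract_stacks(test.images)
_, rss = model.forward(test_stacks)

pairs = [(interp_ground_truth(int(y), model.n), interp_predicted(r))
         for y, r in zip(test.labels, rss)]
a_int = interpretability_accuracy(pairs)
print(f"interpretability accuracy: {a_int:.1f}%  "
      "(fraction of RSS signs agreeing with the class label)")

road = []
for i in range(10):
    res = explain(model, test_stacks[i])
    prms = [p for p in res.prms if np.ptp(p.map) > 0]
    road.append(road_score_explanation(model, test.images[i], prms,
                                       fraction=0.2, seed=i))
print(f"mean ROAD over 10 images: {np.mean(road):+.3f}  "
      "(positive: salient pixels matter more than non-salient ones)")
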