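"""Run the float reference engine layer by layer on one synthetic tile.

Uses freshly initialised (untrained) weights, so the class map is arbitrary;
the point is the inference contract: a (3, H, W) probability map whose
channels sum to one at every pixel, and an argmax label mask.
"""

import numpy as np

from crownseg import (
    SceneConfig,
    build_unet,
    forward,
    generate_scene,
    init_weights,
    predict_labels,
)

spec = build_unet(8, name="unet-light-half")  # half-width variant: fast on a laptop
weights = init_weights(spec, seed=1)

rgb, truth = generate_scene(SceneConfig(tile_size=64), seed=5)
image = rgb.astype(np.float32).transpose(2, 0, 1) / 255.0

probs = forward(spec, weights, image)
labels = predict_labels(probs)

print(f"input tile:       {image.shape} (RGB, scaled to [0, 1])")
print(f"probability map:  {probs.shape}, channel sums in "
      f"[{probs.sum(axis=0).min():.6f}, {probs.sum(axis=0).max():.6f}]")
print(f"label mask:       {labels.shape}, classes present {sorted(int(v) for v in np.unique(labels))}")
print("with untrained weights the labels are near-uniform noise;")
print("see 05_train_and_evaluate.py for a trained model")
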