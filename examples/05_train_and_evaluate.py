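"""Full loop: synthesise data, train, evaluate, and quantise — desk scale.

Generates 100 synthetic 64x64 tiles (70 train / 30 val), trains a half-width
variant of the lightweight model with the study optimizer settings (Adam,
lr 1e-4 -> 1e-6 cosine, batch 2, 1000 steps), then reports validation
metrics and the float-vs-Q6.10 label agreement.  Takes a couple of minutes
on one CPU core.
"""

import numpy as np

from crownseg import (
    SceneConfig,
    TrainConfig,
    VocDataset,
    accumulate,
    build_unet,
    forward,
    fxp_forward,
    generate_dataset,
    predict_labels,
    train,
)
from crownseg.metrics import summarize

generate_dataset(SceneConfig(tile_size=64), 100, "scratch/example_train_ds", seed=7)
ds = VocDataset.load("scratch/example_train_ds")

spec = build_unet(8, name="unet-light-half")
cfg = TrainConfig(image_size=64, iterations=1000, seed=7, eval_interval=100)
weights, history = train(spec, ds, cfg)

print(f"val loss: {history.val_loss[0]:.3f} -> {history.val_loss[-1]:.3f}")
print(f"best val MIoU: {history.best_val_miou:.3f} (step {history.best_step})")

ct, agreements = None, []
for tile_id in ds.ids("val"):
    img, mask = ds.pair(tile_id)
    labels = predict_labels(forward(spec, weights, img))
    ct = accumulate(labels, mask, ct)
    agreements.append(fxp_forward(spec, weights, img).report.label_agreement)

s = summarize(ct)
print(f"\nvalidation metrics over {len(ds.ids('val'))} tiles:")
print(f"  pixel accuracy: {s['pixel_accuracy']:.3f}")
print(f"  MPA:            {s['mean_pixel_accuracy']:.3f}")
print(f"  MIoU:           {s['mean_iou']:.3f}")
for name, vals in s["per_class"].items():
    print(f"  {name}: " + ", ".join(f"{k} {v:.3f}" for k, v in vals.items()))
print(f"\nfloat vs Q6.10 hybrid label agreement: {np.mean(agreements):.4f}")
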