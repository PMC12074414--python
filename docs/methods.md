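# Methods

## Architectures

Both networks are encoder–decoder fully-convolutional models over square RGB
tiles. The encoder is the VGG16 convolutional backbone: five blocks of
2, 2, 3, 3, 3 same-padded 3×3 convolutions (stride 1, zero padding 1, ReLU),
with a 2×2/stride-2 max pool after each of the first four blocks. The
decoder mirrors it with four stages of corner-aligned bilinear 2×
upsampling, concatenation of the same-scale pre-pool encoder output, and two
3×3 convolutions; a final 1×1 convolution maps to the three class logits and
a pixel-wise softmax. That gives 22 convolutions, 4 pools and 4 upsamplings
— 30 counted layers (ReLU is treated as fused layer metadata, and
concatenation as wiring, not layers).

* **baseline U-Net** — encoder widths 64,64 | 128,128 | 256×3 | 512×3 |
  512×3, decoder 512,512 | 256,256 | 128,128 | 64,64, head 64→3.
* **U-Net-light** — the same topology with every internal width divided
  by 4, so the two 512-wide stages become two 128-wide stages (the "split
  bottom"): 16,16 | 32,32 | 64×3 | 128×3 | 128×3, decoder 128,128 … 16,16.

Parameters per convolution are `Co·(Ci·Kw·Kh + 1)` (one bias per output
channel); summing gives 1,557,219 vs 24,891,267 — the kernel tensors scale
exactly 16× except at the 3-channel input and 3-class head, which scale 4×.
MACs are counted as one multiply–accumulate per kernel tap per output pixel;
FLOPs are reported as 2·MAC + bias adds. FLOP totals are
convention-dependent (what counts as an op, whether pool/upsample are
included), so only the light/baseline *ratio* — input-size invariant, 93.7 %
reduction — is treated as exact; absolute totals are sanity-checked at the
few-percent level against the tens/hundreds-of-GFLOP scale.

Two open choices are fixed and documented here: the decoder concatenates
`[encoder skip, upsampled decoder]` in that channel order, and the 1×1 head
has no ReLU (softmax only). Inputs must be square with side a multiple of 8
(byte alignment and four clean halvings) and at least 16; sides outside
{64, 128, 256, 512} are accepted with a warning. `build_unet(width_divisor)`
generalises both models to further-reduced variants with identical topology,
used for desk-scale experiments.

## Reference engine

Float32 throughout. Convolution is evaluated as an im2col matrix product —
algebraically identical to the sliding-window sum, and tested against
literal loop transcriptions at 1e-6. Corner-aligned bilinear upsampling is
implemented as a separable linear operator `M x Mᵀ` where row r of M reads
source coordinate `r·(n_in−1)/(n_out−1)` and blends the two flanking
samples; the four corners are preserved exactly and upsampling to the same
size is the identity. Argmax ties in label prediction resolve to the lowest
class index, for determinism.

## Q6.10 fixed-point emulation

The accelerator's numerics are emulated bit-exactly, not cycle-accurately:

* **Quantisation**: raw = clamp(round-half-to-even(x·2¹⁰), −32768, 32767).
  Round-half-to-even was chosen for unbiasedness and portability (the
  rounding mode of the hardware is not otherwise pinned down); saturation is
  silent but counted.
* **Convolution**: raw products are accumulated exactly in a wide integer
  register (Q12.20 scale; the emulator checks the hardware's 32-bit bound
  and raises on overflow), the raw bias enters left-shifted by 10 bits
  ("bias before write-back"), and one single round-half-to-even shift plus
  saturation produces the Q6.10 output. One rounding per output value makes
  the result reproducible to the bit and checkable against an exact rational
  oracle.
* **Modes**: `hybrid` runs pooling/upsampling in float on dequantised maps
  (the deployed software/hardware split); `full_fxp` keeps pooling in the
  integer domain, where it is exact. Upsampling is float-then-requantise in
  both modes since its blend weights are not Q-format values. Whether the
  deployed software side used floats or fixed point is not documented; both
  are provided.
* **Cap**: input tiles above 128×128 are rejected, mirroring the
  accelerator's sizing.

ReLU and max-pool are exact in the raw integer domain. Bias is quantised to
Q6.10 like the weights.

## Metrics

All metrics derive from a 3×3 truth-by-prediction pixel-count table.
PA = trace/total (the standard multi-class aggregation of the two-class
accuracy ratio). Per-class CPA is implemented literally in its precision
form TP/(TP+FP); some literature uses recall here, so `summarize` labels the
quantity `cpa` explicitly. A class absent from a ratio's denominator is
excluded from MPA/MIoU means, keeping perfect predictions at 1.0; since
whether background belongs in the reported means is a convention,
`summarize` reports both with-background and foreground-only means.

## Synthetic scenes

The generator emulates the *structure* of the study data, not its
radiometry: 1:1 RGB tiles; crowns as unions of 3–7 jittered disks (irregular
quasi-circular blobs) with per-crown colour jitter, blocky texture noise
(fine/dark for conifer, coarser/lighter for broadleaf) and radial edge
shading; background with low-frequency soil/grass patchiness and an optional
grey road stripe; later crowns occlude earlier ones. Each tile is dominated
by a single species, alternating, so a 100-tile dataset has 50 tiles per
species and the three qualitative scene types (conifer, conifer with road,
broadleaf). Datasets are written in exact VOC2012 layout with palette PNGs
whose pixel values are the labels (index 1 renders green, 2 red); the split
is 7:3 per species.

Determinism: one master seed feeds a seed sequence that spawns per-tile
child seeds, so datasets are extensible without reshuffling, and the
hold-out test set uses a disjoint stream. A `jitter_scale` knob widens all
colour distributions to probe domain shift.

What passing tests on these scenes show — and do not show: the classes are
separable mainly by colour/texture, with no shadows, no overlapping canopy
ambiguity, no seasonal or illumination variation, and no annotation noise.
Success here validates the pipeline (data → training → quantised inference →
metrics), not field accuracy on real forests.

## Training

Unweighted pixel-wise softmax cross-entropy (class weighting available via
config). Adam with β₁ = 0.9, β₂ = 0.999, no weight decay, batch 2. The
learning rate decays from 1e-4 to 1e-6; only the endpoints are prescribed by
the study configuration, so the shape is cosine by default with step decay
as an option. "1000 iterations" is read as 1000 optimizer steps; an epoch
interpretation is available via `iteration_unit`. Initialisation is
He-uniform kernels and zero biases; no pretrained encoder weights and no
augmentation. Gradients are a manual reverse-mode pass over the five
operators (checked against finite differences at 1e-2 relative on float32);
runs are seed-deterministic, and the returned checkpoint is the one with the
best validation MIoU.

Weights export to a flat binary sidecar (per layer: name, kernel shape, raw
little-endian float32 kernels and biases; payload exactly 4 bytes per
parameter) that round-trips bit-exactly into both engines; a quantised
Q6.10 variant of the sidecar carries raw int16 values.

## Desk-scale problem sizes

The bundled end-to-end run uses 100 tiles of 64×64 (70/30 split), a
half-width variant of the lightweight model (`build_unet(8)`, same 30-layer
topology), and the study optimizer settings including its 1000 steps; this
trains in about a minute on one CPU core and reaches validation MIoU ≈ 0.80
with ≥ 98 % label agreement between float and Q6.10 hybrid inference. These
sizes were chosen so the whole loop stays interactive on a single core; the
field-scale accuracies reported for the real forest plots require the
original imagery and are out of scope here — the synthetic run verifies
behaviourally (loss decrease, class separation, quantisation robustness),
not numerically.

## Known limitations

* No batching in the inference engines (training batches internally).
* No strides ≠ 1, dilation, grouping or batch normalisation — none occur in
  these architectures.
* The fixed-point emulator models numerics only; no cycle, resource or power
  modelling of the accelerator.
* Synthetic scenes are deliberately simple; see above for what they do not
  emulate.
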