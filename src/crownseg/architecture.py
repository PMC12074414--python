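"""Declarative U-Net-light / U-Net architecture specs and exact accounting.

The segmentation networks handled here are VGG16-backbone encoder–decoder
models for three-class crown segmentation (background, *Pinus tabuliformis*,
*Salix matsudana*).  A :class:`ModelSpec` is an ordered list of layer
descriptors and is the single source of truth used to build, profile and run
a network: parameter counting, MAC/FLOP accounting, layer censuses, weight
initialisation and both inference engines all walk the same spec.

Two concrete builders are provided:

* :func:`build_unet_light` — the lightweight model: VGG16-style encoder with
  channel widths reduced to one quarter and the 256-channel bottom split into
  two 128-channel blocks (encoder conv widths 16,16 | 32,32 | 64,64,64 |
  128,128,128 | 128,128,128), a four-stage decoder with skip concatenations,
  and a 1x1 three-class head.  22 convolutions, 4 maxpools, 4 upsamplings.
* :func:`build_unet_baseline` — the same topology at full width (every
  internal channel count times 4), the comparison baseline.

All convolutions are stride 1 with same-padding, so every layer preserves
spatial size and the network accepts any square input whose side is a
multiple of 8 (needed for four clean 2x halvings plus byte alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import yaml

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "conv_param_count",
    "build_unet",
    "build_unet_light",
    "build_unet_baseline",
    "model_param_total",
    "model_mac_total",
    "ComputeProfile",
    "layer_census",
    "validate_input_size",
    "spec_to_yaml",
    "spec_from_yaml",
]

LAYER_KINDS = ("conv3x3", "conv1x1", "maxpool2", "upsample2x", "concat_skip")

#: Input sides the study images actually used; anything else square and
#: divisible by 8 still runs, but we warn so typos surface early.
_STUDY_SIZES = (64, 128, 256, 512)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of an encoder–decoder segmentation network.

    ``spatial_scale`` is the power-of-two divisor of the input resolution at
    which the layer operates (1 at full resolution, 16 at the bottom of the
    U).  ``skip_source`` names the earlier layer whose output a
    ``concat_skip`` prepends along the channel axis.  ``activation`` is layer
    metadata (fused with the conv, not a counted layer): ``"relu"`` or
    ``None``.
    """

    name: str
    kind: str
    in_channels: int
    out_channels: int
    spatial_scale: int = 1
    skip_source: Optional[str] = None
    activation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError(f"{self.name}: channel counts must be >= 1")
        if self.kind == "concat_skip" and not self.skip_source:
            raise ValueError(f"{self.name}: concat_skip requires skip_source")
        if self.kind != "concat_skip" and self.skip_source:
            raise ValueError(f"{self.name}: only concat_skip takes skip_source")
        if self.spatial_scale < 1 or self.spatial_scale & (self.spatial_scale - 1):
            raise ValueError(f"{self.name}: spatial_scale must be a power of two")

    @property
    def is_conv(self) -> bool:
        return self.kind in ("conv3x3", "conv1x1")

    @property
    def kernel(self) -> int:
        if self.kind == "conv3x3":
            return 3
        if self.kind == "conv1x1":
            return 1
        raise AttributeError(f"{self.name} ({self.kind}) has no kernel")


@dataclass
class ModelSpec:
    """Ordered layer list plus the fixed input/output contract."""

    layers: list[LayerSpec] = field(default_factory=list)
    num_classes: int = 3
    input_channels: int = 3
    name: str = "model"

    def validate(self) -> None:
        """Walk the graph and check channel bookkeeping and skip wiring."""
        by_name: dict[str, LayerSpec] = {}
        current = self.input_channels
        scale = 1
        heads = 0
        for layer in self.layers:
            if layer.name in by_name:
                raise ValueError(f"duplicate layer name {layer.name!r}")
            if layer.kind == "maxpool2":
                scale *= 2
            elif layer.kind == "upsample2x":
                scale //= 2
                if scale < 1:
                    raise ValueError(f"{layer.name}: upsampled above input resolution")
            if layer.kind == "concat_skip":
                src = by_name.get(layer.skip_source)  # type: ignore[arg-type]
                if src is None:
                    raise ValueError(
                        f"{layer.name}: skip_source {layer.skip_source!r} "
                        "does not name an earlier layer"
                    )
                if src.spatial_scale != scale:
                    raise ValueError(
                        f"{layer.name}: skip from scale 1/{src.spatial_scale} "
                        f"into scale 1/{scale}"
                    )
                expected_in = current
                expected_out = current + src.out_channels
            else:
                expected_in = current
                expected_out = {
                    "conv3x3": layer.out_channels,
                    "conv1x1": layer.out_channels,
                    "maxpool2": current,
                    "upsample2x": current,
                }[layer.kind]
            if layer.in_channels != expected_in:
                raise ValueError(
                    f"{layer.name}: declares in_channels={layer.in_channels}, "
                    f"predecessor provides {expected_in}"
                )
            if layer.out_channels != expected_out:
                raise ValueError(
                    f"{layer.name}: declares out_channels={layer.out_channels}, "
                    f"computed {expected_out}"
                )
            if layer.spatial_scale != scale:
                raise ValueError(
                    f"{layer.name}: declares scale 1/{layer.spatial_scale}, "
                    f"graph walk gives 1/{scale}"
                )
            if layer.kind == "conv1x1":
                heads += 1
            current = expected_out
            by_name[layer.name] = layer
        if self.layers:
            if heads != 1:
                raise ValueError(f"expected exactly one conv1x1 head, found {heads}")
            if current != self.num_classes:
                raise ValueError(
                    f"network emits {current} channels, num_classes={self.num_classes}"
                )

    @property
    def conv_layers(self) -> list[LayerSpec]:
        return [l for l in self.layers if l.is_conv]

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


def conv_param_count(co: int, ci: int, kh: int, kw: int) -> int:
    """Trainable parameters of one convolution: ``co * (ci*kw*kh + 1)``.

    One bias per output channel is included, hence the ``+ 1``.
    """
    if min(co, ci, kh, kw) < 1:
        raise ValueError("all of co, ci, kh, kw must be >= 1")
    return co * (ci * kw * kh + 1)


def _encoder_blocks(width_divisor: int) -> list[list[int]]:
    # VGG16 conv widths 64,64 | 128,128 | 256x3 | 512x3 | 512x3, divided.
    # At divisor 4 the 512-channel stages become two 128-channel stages:
    # the "split 256-channel bottom" of the lightweight design.
    blocks = [[64, 64], [128, 128], [256] * 3, [512] * 3, [512] * 3]
    return [[c // width_divisor for c in b] for b in blocks]


def _decoder_blocks(width_divisor: int) -> list[list[int]]:
    blocks = [[512, 512], [256, 256], [128, 128], [64, 64]]
    return [[c // width_divisor for c in b] for b in blocks]


def build_unet(width_divisor: int = 1, num_classes: int = 3, name: str | None = None) -> ModelSpec:
    """Build the VGG16-backbone encoder–decoder at a given width.

    ``width_divisor=1`` is the full-channel baseline U-Net, ``4`` the
    lightweight model.  Larger powers of two give further-reduced variants
    used for desk-scale training experiments; the topology (and therefore
    layer census) never changes.
    """
    if width_divisor < 1 or 64 % width_divisor:
        raise ValueError("width_divisor must divide 64")
    layers: list[LayerSpec] = []
    cin = 3
    scale = 1
    skip_names: list[str] = []

    def conv(nm: str, kind: str, co: int, act: Optional[str] = "relu") -> None:
        nonlocal cin
        layers.append(LayerSpec(nm, kind, cin, co, scale, activation=act))
        cin = co

    for bi, widths in enumerate(_encoder_blocks(width_divisor), start=1):
        for ci_idx, co in enumerate(widths, start=1):
            conv(f"conv{bi}-{ci_idx}", "conv3x3", co)
        if bi < 5:
            skip_names.append(layers[-1].name)
            scale *= 2  # spatial_scale records each layer's output scale
            layers.append(LayerSpec(f"maxpool{bi}", "maxpool2", cin, cin, scale))
    for di, widths in enumerate(_decoder_blocks(width_divisor), start=1):
        scale //= 2
        layers.append(LayerSpec(f"upsample{di}", "upsample2x", cin, cin, scale))
        src = skip_names[-di]
        src_out = next(l.out_channels for l in layers if l.name == src)
        layers.append(
            LayerSpec(
                f"concat{di}", "concat_skip", cin, cin + src_out, scale, skip_source=src
            )
        )
        cin += src_out
        for ci_idx, co in enumerate(widths, start=1):
            conv(f"conv{di + 5}-{ci_idx}", "conv3x3", co)
    conv("conv10", "conv1x1", num_classes, act=None)

    spec = ModelSpec(
        layers,
        num_classes=num_classes,
        name=name or (f"unet-light" if width_divisor == 4 else f"unet/{width_divisor}"),
    )
    spec.validate()
    return spec


def build_unet_light() -> ModelSpec:
    """The lightweight crown-segmentation model (quarter-width VGG16 U-Net)."""
    return build_unet(width_divisor=4, name="unet-light")


def build_unet_baseline() -> ModelSpec:
    """The full-channel baseline U-Net the lightweight model is compared to."""
    return build_unet(width_divisor=1, name="unet")


def model_param_total(spec: ModelSpec) -> int:
    """Total trainable parameters: the per-conv count summed over all convs.

    Pooling, upsampling and concatenation carry no parameters.
    """
    return sum(
        conv_param_count(l.out_channels, l.in_channels, l.kernel, l.kernel)
        for l in spec.conv_layers
    )


@dataclass(frozen=True)
class ComputeProfile:
    """MAC/FLOP accounting of a spec at one input size.

    ``macs`` counts one multiply–accumulate per kernel tap per output pixel;
    ``flops`` uses the common 2*MAC-plus-bias-add convention.  Absolute FLOP
    totals depend on such conventions; ratios between two specs do not.
    """

    macs: int
    flops: int
    input_size: int

    @property
    def gflops(self) -> float:
        return self.flops / 1e9


def model_mac_total(spec: ModelSpec, input_size: int) -> ComputeProfile:
    """Multiply–accumulate count of all convolutions at a square input size."""
    if not validate_input_size(input_size, input_size):
        raise ValueError(
            f"input_size {input_size} invalid: need a square multiple of 8, >= 16"
        )
    macs = 0
    bias_adds = 0
    for l in spec.conv_layers:
        hw = (input_size // l.spatial_scale) ** 2
        macs += hw * l.out_channels * l.in_channels * l.kernel * l.kernel
        bias_adds += hw * l.out_channels
    return ComputeProfile(macs=macs, flops=2 * macs + bias_adds, input_size=input_size)


def layer_census(spec: ModelSpec) -> dict[str, int]:
    """Count layers per kind.  Concatenation is wiring, not a counted layer."""
    census = {k: 0 for k in LAYER_KINDS}
    for l in spec.layers:
        census[l.kind] += 1
    return census


def counted_layer_total(spec: ModelSpec) -> int:
    """Total network depth as conventionally counted: convs + pools + upsamples."""
    c = layer_census(spec)
    return c["conv3x3"] + c["conv1x1"] + c["maxpool2"] + c["upsample2x"]


def validate_input_size(h: int, w: int) -> bool:
    """True iff ``h == w``, ``h`` is a multiple of 8 and ``h >= 16``.

    Square multiple-of-8 inputs keep feature-map rows byte-aligned and
    survive the four 2x halvings; below 16 the bottom of the U would
    collapse under one pixel.  Sizes outside the study set {64, 128, 256,
    512} are accepted with a warning.
    """
    ok = h == w and h % 8 == 0 and h >= 16
    if ok and h not in _STUDY_SIZES:
        warnings.warn(
            f"input size {h} is valid but outside the study sizes {_STUDY_SIZES}",
            stacklevel=2,
        )
    return ok


# --- YAML (de)serialisation -------------------------------------------------

def spec_to_yaml(spec: ModelSpec) -> str:
    doc = {
        "name": spec.name,
        "num_classes": spec.num_classes,
        "input_channels": spec.input_channels,
        "layers": [
            {
                k: v
                for k, v in {
                    "name": l.name,
                    "kind": l.kind,
                    "in_channels": l.in_channels,
                    "out_channels": l.out_channels,
                    "spatial_scale": l.spatial_scale,
                    "skip_source": l.skip_source,
                    "activation": l.activation,
                }.items()
                if v is not None
            }
            for l in spec.layers
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> ModelSpec:
    doc = yaml.safe_load(text)
    spec = ModelSpec(
        layers=[LayerSpec(**d) for d in doc["layers"]],
        num_classes=doc.get("num_classes", 3),
        input_channels=doc.get("input_channels", 3),
        name=doc.get("name", "model"),
    )
    spec.validate()
    return spec
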