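"""Float32 reference inference engine.

Implements the handful of operators the crown-segmentation networks are made
of — same-padded convolution, ReLU, 2x2 max pooling, corner-aligned bilinear
upsampling and pixel-wise softmax — and a :func:`forward` pass that executes
any :class:`~crownseg.architecture.ModelSpec` with skip concatenation.  This
engine is the numerical ground truth that the Q6.10 fixed-point emulator is
measured against.

Feature maps are ``(channels, rows, cols)`` float32 arrays.  Convolution is
evaluated as an im2col matrix product, which is numerically equivalent to
the naive sliding-window sum (the tests compare the two to 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .architecture import ModelSpec, validate_input_size

__all__ = [
    "FeatureMap",
    "ConvWeights",
    "conv2d",
    "relu",
    "maxpool2",
    "upsample_bilinear",
    "softmax_pixelwise",
    "forward",
    "forward_logits",
    "predict_labels",
]


@dataclass
class FeatureMap:
    """Rank-3 feature map with an explicit dtype tag (float32 or qint16)."""

    data: np.ndarray
    dtype_tag: str = "float32"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("feature maps are (channels, rows, cols)")
        if min(self.data.shape) < 1:
            raise ValueError("empty feature map")
        if self.dtype_tag not in ("float32", "qint16"):
            raise ValueError(f"unknown dtype tag {self.dtype_tag!r}")

    @property
    def channels(self) -> int:
        return self.data.shape[0]


@dataclass
class ConvWeights:
    """Kernels ``(filters, in_channels, kh, kw)`` plus one bias per filter."""

    kernels: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        if self.kernels.ndim != 4:
            raise ValueError("kernels are (filters, in_channels, kh, kw)")
        kh, kw = self.kernels.shape[2:]
        if kh != kw or kh not in (1, 3):
            raise ValueError("only square 1x1 and 3x3 kernels are supported")
        if self.bias.shape != (self.kernels.shape[0],):
            raise ValueError("bias must have one entry per filter")

    @property
    def filters(self) -> int:
        return self.kernels.shape[0]

    @property
    def in_channels(self) -> int:
        return self.kernels.shape[1]

    @property
    def kernel_size(self) -> int:
        return self.kernels.shape[2]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, FeatureMap) else np.asarray(x)


def im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold ``(C, H, W)`` into ``(C*k*k, H*W)`` patch columns (stride 1)."""
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    # sliding_window_view gives (C, H, W, k, k) for same-size output
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return win.transpose(0, 3, 4, 1, 2).reshape(c * k * k, h * w)


def conv2d(x, w: ConvWeights):
    """Same-padded stride-1 convolution (cross-correlation orientation).

    3x3 kernels use zero-padding 1, 1x1 kernels no padding; output spatial
    size always equals input spatial size.
    """
    arr = _as_array(x).astype(np.float32, copy=False)
    if arr.shape[0] != w.in_channels:
        raise ValueError(
            f"input has {arr.shape[0]} channels, weights expect {w.in_channels}"
        )
    k = w.kernel_size
    pad = 1 if k == 3 else 0
    _, h, wid = arr.shape
    cols = im2col(arr, k, pad)
    mat = w.kernels.reshape(w.filters, -1).astype(np.float32, copy=False)
    out = mat @ cols + w.bias.astype(np.float32)[:, None]
    return out.reshape(w.filters, h, wid)


def relu(x):
    """Elementwise ``max(0, x)``."""
    return np.maximum(_as_array(x), 0)


def maxpool2(x):
    """2x2 max pooling with stride 2; rows and cols must be even."""
    arr = _as_array(x)
    c, h, w = arr.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even dimensions, got {h}x{w}")
    return arr.reshape(c, h // 2, 2, w // 2, 2).max(axis=(2, 4))


def upsample_matrix(size_in: int, size_out: int, dtype=np.float64) -> np.ndarray:
    """Corner-aligned linear interpolation matrix ``(size_out, size_in)``.

    Output sample ``r`` reads source coordinate ``r * (size_in-1)/(size_out-1)``
    and blends the two flanking samples linearly; row 0 and the last row are
    exactly the first and last input samples (corner alignment).  Applied to
    rows and columns separately this reproduces four-neighbour bilinear
    interpolation.
    """
    if size_out < 2:
        raise ValueError("output size must be >= 2")
    m = np.zeros((size_out, size_in), dtype=dtype)
    if size_in == 1:
        m[:, 0] = 1.0
        return m
    scale = (size_in - 1.0) / (size_out - 1.0)
    for r in range(size_out):
        x = r * scale
        xi = int(x)
        xa = x - xi
        if xi >= size_in - 1:  # exact top corner
            m[r, size_in - 1] = 1.0
        else:
            m[r, xi] = 1.0 - xa
            m[r, xi + 1] = xa
    return m


def upsample_bilinear(x, size_out: int):
    """Corner-aligned bilinear upsampling of a square map to ``size_out``."""
    arr = _as_array(x)
    c, h, w = arr.shape
    if h != w:
        raise ValueError("upsampling expects a square map")
    if size_out < 2:
        raise ValueError("output size must be >= 2")
    m = upsample_matrix(h, size_out, dtype=np.float32)
    # out[c] = M @ x[c] @ M.T, done as two tensordots
    tmp = np.tensordot(arr, m, axes=([1], [1]))  # (c, w, out_rows)
    out = np.tensordot(tmp, m, axes=([1], [1]))  # (c, out_rows, out_cols)
    return np.ascontiguousarray(out)


def softmax_pixelwise(logits):
    """Per-pixel softmax over the channel axis, max-stabilised."""
    arr = _as_array(logits).astype(np.float64, copy=False)
    shifted = arr - arr.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return (e / e.sum(axis=0, keepdims=True)).astype(np.float32)


def _check_weights(spec: ModelSpec, weights: Sequence[ConvWeights]) -> None:
    convs = spec.conv_layers
    if len(weights) != len(convs):
        raise ValueError(
            f"{spec.name}: spec has {len(convs)} conv layers, got {len(weights)} weight sets"
        )
    for layer, w in zip(convs, weights):
        if (
            w.filters != layer.out_channels
            or w.in_channels != layer.in_channels
            or w.kernel_size != layer.kernel
        ):
            raise ValueError(
                f"layer {layer.name}: expects "
                f"({layer.out_channels},{layer.in_channels},{layer.kernel},{layer.kernel}), "
                f"got ({w.filters},{w.in_channels},{w.kernel_size},{w.kernel_size})"
            )


def forward_logits(spec: ModelSpec, weights: Sequence[ConvWeights], image) -> np.ndarray:
    """Run the network up to (and including) the head, without softmax."""
    x = _as_array(image).astype(np.float32, copy=False)
    if not validate_input_size(x.shape[1], x.shape[2]):
        raise ValueError(f"invalid input size {x.shape[1]}x{x.shape[2]}")
    if x.shape[0] != spec.input_channels:
        raise ValueError(
            f"image has {x.shape[0]} channels, spec expects {spec.input_channels}"
        )
    _check_weights(spec, weights)
    wi = iter(weights)
    cache: dict[str, np.ndarray] = {}
    for layer in spec.layers:
        if layer.is_conv:
            x = conv2d(x, next(wi))
            if layer.activation == "relu":
                x = relu(x)
        elif layer.kind == "maxpool2":
            x = maxpool2(x)
        elif layer.kind == "upsample2x":
            x = upsample_bilinear(x, x.shape[1] * 2)
        elif layer.kind == "concat_skip":
            skip = cache[layer.skip_source]  # validated by spec.validate()
            x = np.concatenate([skip, x], axis=0)
        cache[layer.name] = x
    return x


def forward(spec: ModelSpec, weights: Sequence[ConvWeights], image) -> np.ndarray:
    """Full forward pass: class-probability map ``(num_classes, H, W)``."""
    return softmax_pixelwise(forward_logits(spec, weights, image))


def predict_labels(probs_or_logits) -> np.ndarray:
    """Argmax label mask; ties resolve to the lowest class index."""
    return np.argmax(_as_array(probs_or_logits), axis=0).astype(np.uint8)
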