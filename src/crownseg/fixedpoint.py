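"""Bit-accurate Q6.10 fixed-point inference emulation.

The deployed accelerator computes convolutions in signed 16-bit fixed point
with 6 integer bits (sign included) and 10 fractional bits: representable
range [-32, 31.9990234375], resolution 2^-10.  Products of raw values are
accumulated exactly in a wide integer register (Q12.20 scale), the raw bias
is aligned into the accumulator by a left shift of ``frac_bits``, and a
single round-half-to-even right shift with saturation produces the output at
write-back.  Because there is exactly one rounding per output value, the
emulation is bit-identical across platforms and can be checked against an
arbitrary-precision rational oracle.

Pooling and upsampling run outside the accelerator.  Two inference modes are
offered: ``hybrid`` (pool and upsample in float on dequantised maps, as when
a host CPU handles them) and ``full_fxp`` (pooling stays in the integer
domain — exact, since the max of representable values is representable —
and upsampling is float-then-requantise).

The accelerator accepts input tiles up to 128x128.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .architecture import ModelSpec, validate_input_size
from .reference import (
    ConvWeights,
    forward_logits,
    im2col,
    maxpool2,
    predict_labels,
    softmax_pixelwise,
    upsample_bilinear,
)

__all__ = [
    "QFormat",
    "Q6_10",
    "QTensor",
    "QConvWeights",
    "FxpOverflowError",
    "AcceleratorCapError",
    "quantize",
    "dequantize",
    "quantize_weights",
    "fxp_conv2d",
    "fxp_forward",
    "FxpResult",
    "quantization_report",
    "QuantizationReport",
    "ACCELERATOR_MAX_SIZE",
]

#: Largest square input tile the accelerator was sized for.
ACCELERATOR_MAX_SIZE = 128


class FxpOverflowError(OverflowError):
    """The wide accumulator left the 32-bit range the hardware provides."""


class AcceleratorCapError(ValueError):
    """Input exceeds the accelerator's 128x128 maximum tile size."""


@dataclass(frozen=True)
class QFormat:
    """Signed fixed-point format: ``int_bits`` (incl. sign) + ``frac_bits``."""

    total_bits: int = 16
    int_bits: int = 6
    frac_bits: int = 10

    def __post_init__(self) -> None:
        if self.int_bits + self.frac_bits != self.total_bits:
            raise ValueError("int_bits + frac_bits must equal total_bits")
        if self.int_bits < 1 or self.frac_bits < 0:
            raise ValueError("need at least a sign bit and non-negative frac_bits")

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def min_real(self) -> float:
        return self.raw_min / self.scale

    @property
    def max_real(self) -> float:
        return self.raw_max / self.scale

    @property
    def resolution(self) -> float:
        return 1.0 / self.scale


Q6_10 = QFormat(16, 6, 10)


@dataclass
class QTensor:
    """Integer array of raw values (real value times ``2**frac_bits``).

    ``saturated`` counts elements clipped to the format range when the
    tensor was produced (quantisation or convolution write-back).
    """

    raw: np.ndarray
    fmt: QFormat = Q6_10
    saturated: int = 0

    def __post_init__(self) -> None:
        r = self.raw
        if r.dtype.kind != "i":
            raise TypeError("raw values must be integers")
        if r.size and (r.min() < self.fmt.raw_min or r.max() > self.fmt.raw_max):
            raise ValueError("raw values outside the format range")

    @property
    def real(self) -> np.ndarray:
        return dequantize(self)


def quantize(x, fmt: QFormat = Q6_10) -> QTensor:
    """Round-half-to-even quantisation with silent (but counted) saturation."""
    arr = np.asarray(x, dtype=np.float64)
    scaled = np.rint(arr * fmt.scale)  # rint rounds half to even
    clipped = np.clip(scaled, fmt.raw_min, fmt.raw_max)
    saturated = int(np.count_nonzero(scaled != clipped))
    return QTensor(clipped.astype(np.int64), fmt, saturated)


def dequantize(q: QTensor) -> np.ndarray:
    return (q.raw / q.fmt.scale).astype(np.float64)


@dataclass
class QConvWeights:
    """Pre-quantised convolution weights: raw kernels and raw bias."""

    kernels: QTensor
    bias: QTensor

    @property
    def fmt(self) -> QFormat:
        return self.kernels.fmt


def quantize_weights(w: ConvWeights, fmt: QFormat = Q6_10) -> QConvWeights:
    return QConvWeights(quantize(w.kernels, fmt), quantize(w.bias, fmt))


def _round_shift_half_even(acc: np.ndarray, shift: int) -> np.ndarray:
    """Arithmetic right shift by ``shift`` with round-half-to-even."""
    if shift == 0:
        return acc
    floor = acc >> shift
    rem = acc & ((1 << shift) - 1)
    half = 1 << (shift - 1)
    round_up = (rem > half) | ((rem == half) & ((floor & 1) == 1))
    return floor + round_up


_ACC_MIN, _ACC_MAX = -(1 << 31), (1 << 31) - 1


def fxp_conv2d(x: QTensor, w: QConvWeights, fmt: Optional[QFormat] = None) -> QTensor:
    """Fixed-point same-padded convolution with a single write-back rounding.

    Raw products accumulate exactly in int64 (the hardware's tree adder at
    Q12.20 scale); the raw bias enters the accumulator left-shifted by
    ``frac_bits``; one round-half-to-even shift plus saturation yields the
    output.  An accumulator outside the signed 32-bit range raises
    :class:`FxpOverflowError` — in-range activations through networks of up
    to 256 input channels stay well inside it.
    """
    fmt = fmt or w.fmt
    if x.fmt != fmt or w.fmt != fmt:
        raise ValueError("input, weights and target format must agree")
    kern = w.kernels.raw
    co, ci, k, _ = kern.shape
    if x.raw.shape[0] != ci:
        raise ValueError(f"input has {x.raw.shape[0]} channels, weights expect {ci}")
    pad = 1 if k == 3 else 0
    _, h, wid = x.raw.shape
    cols = im2col(x.raw.astype(np.int64), k, pad)
    acc = kern.reshape(co, -1).astype(np.int64) @ cols
    acc += (w.bias.raw.astype(np.int64) << fmt.frac_bits)[:, None]
    if acc.size and (acc.min() < _ACC_MIN or acc.max() > _ACC_MAX):
        raise FxpOverflowError(
            "convolution accumulator exceeded the 32-bit hardware register"
        )
    out = _round_shift_half_even(acc, fmt.frac_bits)
    clipped = np.clip(out, fmt.raw_min, fmt.raw_max)
    saturated = int(np.count_nonzero(out != clipped))
    return QTensor(clipped.reshape(co, h, wid), fmt, saturated)


@dataclass
class FxpResult:
    """Outcome of a fixed-point forward pass plus float-reference divergence."""

    labels: np.ndarray
    logits: np.ndarray  # dequantised head output
    probs: np.ndarray  # softmax of the dequantised logits
    saturated: int
    report: "QuantizationReport"


def fxp_forward(
    spec: ModelSpec,
    weights: Sequence[ConvWeights],
    image,
    mode: str = "hybrid",
    fmt: QFormat = Q6_10,
) -> FxpResult:
    """Emulated accelerator inference on one tile (max 128x128).

    ``hybrid``: convolutions in fixed point, pooling/upsampling in float on
    dequantised maps with requantisation before the next convolution.
    ``full_fxp``: pooling in the integer domain (exact); upsampling is
    float-then-requantise in both modes, as its blend weights are not
    Q-format values.
    """
    if mode not in ("hybrid", "full_fxp"):
        raise ValueError(f"unknown mode {mode!r}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        raise ValueError("image must be (channels, rows, cols)")
    h, wid = img.shape[1:]
    if h > ACCELERATOR_MAX_SIZE or wid > ACCELERATOR_MAX_SIZE:
        raise AcceleratorCapError(
            f"{h}x{wid} exceeds the accelerator's maximum input size of "
            f"{ACCELERATOR_MAX_SIZE}x{ACCELERATOR_MAX_SIZE}"
        )
    if not validate_input_size(h, wid):
        raise ValueError(f"invalid input size {h}x{wid}")

    qweights = [quantize_weights(w, fmt) for w in weights]
    saturated = sum(qw.kernels.saturated + qw.bias.saturated for qw in qweights)

    x = quantize(img, fmt)
    saturated += x.saturated
    qi = iter(qweights)
    cache: dict[str, QTensor] = {}
    for layer in spec.layers:
        if layer.is_conv:
            x = fxp_conv2d(x, next(qi), fmt)
            saturated += x.saturated
            if layer.activation == "relu":
                x = QTensor(np.maximum(x.raw, 0), fmt)  # exact in raw domain
        elif layer.kind == "maxpool2":
            if mode == "full_fxp":
                c, hh, ww = x.raw.shape
                pooled = x.raw.reshape(c, hh // 2, 2, ww // 2, 2).max(axis=(2, 4))
                x = QTensor(pooled, fmt)
            else:
                x = quantize(maxpool2(dequantize(x)), fmt)
                saturated += x.saturated
        elif layer.kind == "upsample2x":
            up = upsample_bilinear(
                dequantize(x).astype(np.float32), x.raw.shape[1] * 2
            )
            x = quantize(up, fmt)
            saturated += x.saturated
        elif layer.kind == "concat_skip":
            x = QTensor(np.concatenate([cache[layer.skip_source].raw, x.raw], axis=0), fmt)
        cache[layer.name] = x

    logits = dequantize(x).astype(np.float32)
    probs = softmax_pixelwise(logits)
    labels = predict_labels(logits)

    float_logits = forward_logits(spec, weights, img.astype(np.float32))
    report = quantization_report(float_logits, logits, saturated=saturated)
    return FxpResult(labels, logits, probs, saturated, report)


@dataclass
class QuantizationReport:
    """Float-vs-fixed-point divergence on one pair of output maps."""

    max_abs_error: float
    mean_abs_error: float
    label_agreement: float
    per_class_agreement: dict[int, float]
    saturated: int = 0


def quantization_report(float_out, fxp_out, saturated: int = 0) -> QuantizationReport:
    """Compare a float map against its fixed-point counterpart.

    Label agreement is the fraction of pixels whose argmax class coincides;
    per-class agreement conditions on the float-reference label.
    """
    a = np.asarray(float_out, dtype=np.float64)
    b = np.asarray(fxp_out, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    err = np.abs(a - b)
    la = predict_labels(a)
    lb = predict_labels(b)
    agree = la == lb
    per_class = {
        int(c): float(agree[la == c].mean()) for c in np.unique(la)
    }
    return QuantizationReport(
        max_abs_error=float(err.max()),
        mean_abs_error=float(err.mean()),
        label_agreement=float(agree.mean()),
        per_class_agreement=per_class,
        saturated=saturated,
    )
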