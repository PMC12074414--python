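"""Float operators against naive-loop oracles and their exact invariants."""

import numpy as np
import pytest

from crownseg.reference import (
    ConvWeights,
    conv2d,
    forward,
    forward_logits,
    maxpool2,
    predict_labels,
    relu,
    softmax_pixelwise,
    upsample_bilinear,
)
from crownseg.training import init_weights

TOL = 1e-6


# --- naive loop oracles (transcribed from the published operator listings) --


def conv_oracle(x, kernels, bias, pad):
    co, ci, k, _ = kernels.shape
    c, h, w = x.shape
    buf = np.zeros((c, h + 2 * pad, w + 2 * pad))
    buf[:, pad : pad + h, pad : pad + w] = x  # zero-value filling
    out = np.zeros((co, h, w))
    for i in range(co):
        for xx in range(h):
            for yy in range(w):
                s = 0.0
                for j in range(ci):
                    for u in range(k):
                        for v in range(k):
                            s += buf[j, xx + u, yy + v] * kernels[i, j, u, v]
                out[i, xx, yy] = s + bias[i]
    return out


def maxpool_oracle(x):
    c, h, w = x.shape
    out = np.empty((c, h // 2, w // 2))
    for i in range(c):
        for j in range(h // 2):
            for k in range(w // 2):
                m = -np.inf
                for l in range(2 * j, 2 * j + 2):
                    for mm in range(2 * k, 2 * k + 2):
                        m = max(m, x[i, l, mm])
                out[i, j, k] = m
    return out


def upsample_oracle(x, size_out):
    c, size_in, _ = x.shape
    out = np.zeros((c, size_out, size_out))
    for ch in range(c):
        for row in range(size_out):
            for col in range(size_out):
                xx = row * (size_in - 1.0) / (size_out - 1.0)
                yy = col * (size_in - 1.0) / (size_out - 1.0)
                xi, yi = int(xx), int(yy)
                xa, ya = xx - xi, yy - yi
                if row < size_out - 1 and col < size_out - 1:
                    out[ch, row, col] = (
                        x[ch, xi, yi] * (1 - xa) * (1 - ya)
                        + x[ch, xi + 1, yi] * xa * (1 - ya)
                        + x[ch, xi, yi + 1] * (1 - xa) * ya
                        + x[ch, xi + 1, yi + 1] * xa * ya
                    )
                elif row == size_out - 1 and col == size_out - 1:
                    out[ch, row, col] = x[ch, xi, yi]
                elif row == size_out - 1:
                    out[ch, row, col] = x[ch, xi, yi] * (1 - ya) + x[ch, xi, yi + 1] * ya
                else:
                    out[ch, row, col] = x[ch, xi, yi] * (1 - xa) + x[ch, xi + 1, yi] * xa
    return out


# --- conv2d -----------------------------------------------------------------


def test_conv_all_ones_hand_case():
    w = ConvWeights(np.ones((1, 1, 3, 3), np.float32), np.zeros(1, np.float32))
    out = conv2d(np.ones((1, 3, 3), np.float32), w)[0]
    assert out[1, 1] == 9  # full 3x3 support
    assert out[0, 1] == out[1, 0] == 6  # edge midpoints
    assert out[0, 0] == out[2, 2] == 4  # corners


@pytest.mark.parametrize("k,ci,co,size", [(3, 1, 1, 5), (3, 3, 4, 8), (1, 4, 2, 6)])
def test_conv_matches_loop_oracle(rng, k, ci, co, size):
    x = rng.normal(size=(ci, size, size)).astype(np.float32)
    w = ConvWeights(
        rng.normal(size=(co, ci, k, k)).astype(np.float32),
        rng.normal(size=co).astype(np.float32),
    )
    expected = conv_oracle(x, w.kernels, w.bias, pad=1 if k == 3 else 0)
    np.testing.assert_allclose(conv2d(x, w), expected, atol=TOL, rtol=TOL)


def test_conv_identity_1x1():
    x = np.random.default_rng(0).normal(size=(3, 4, 4)).astype(np.float32)
    eye = np.eye(3, dtype=np.float32).reshape(3, 3, 1, 1)
    w = ConvWeights(eye, np.zeros(3, np.float32))
    np.testing.assert_array_equal(conv2d(x, w), x)


def test_conv_bias_only():
    w = ConvWeights(np.zeros((2, 1, 3, 3), np.float32), np.array([1.5, -2.0], np.float32))
    out = conv2d(np.random.default_rng(1).normal(size=(1, 4, 4)).astype(np.float32), w)
    assert (out[0] == 1.5).all() and (out[1] == -2.0).all()


def test_conv_is_linear_in_input(rng):
    x = rng.normal(size=(2, 6, 6)).astype(np.float32)
    y = rng.normal(size=(2, 6, 6)).astype(np.float32)
    w = ConvWeights(rng.normal(size=(3, 2, 3, 3)).astype(np.float32), np.zeros(3, np.float32))
    lhs = conv2d(2.0 * x + 3.0 * y, w)
    rhs = 2.0 * conv2d(x, w) + 3.0 * conv2d(y, w)
    np.testing.assert_allclose(lhs, rhs, atol=1e-4)


def test_conv_translation_equivariance_away_from_border(rng):
    x = np.zeros((1, 9, 9), np.float32)
    x[0, 2:5, 2:5] = rng.normal(size=(3, 3))
    w = ConvWeights(rng.normal(size=(1, 1, 3, 3)).astype(np.float32), np.zeros(1, np.float32))
    shifted = np.roll(x, (2, 2), axis=(1, 2))
    out, out_shifted = conv2d(x, w), conv2d(shifted, w)
    np.testing.assert_allclose(
        np.roll(out, (2, 2), axis=(1, 2))[0, 3:7, 3:7], out_shifted[0, 3:7, 3:7], atol=TOL
    )


def test_conv_channel_mismatch_raises(rng):
    w = ConvWeights(rng.normal(size=(1, 2, 3, 3)).astype(np.float32), np.zeros(1, np.float32))
    with pytest.raises(ValueError, match="channels"):
        conv2d(np.zeros((3, 4, 4), np.float32), w)


# --- relu / maxpool ---------------------------------------------------------


def test_relu_cases():
    np.testing.assert_array_equal(relu(np.array([[[-1.0, 0.0, 2.0]]])), [[[0, 0, 2]]])
    x = np.abs(np.random.default_rng(2).normal(size=(2, 3, 3)))
    np.testing.assert_array_equal(relu(x), x)
    y = np.random.default_rng(3).normal(size=(2, 3, 3))
    np.testing.assert_array_equal(relu(relu(y)), relu(y))


def test_maxpool_cases(rng):
    np.testing.assert_array_equal(maxpool2(np.array([[[1.0, 2.0], [3.0, 4.0]]])), [[[4.0]]])
    const = np.full((3, 4, 4), 2.5)
    np.testing.assert_array_equal(maxpool2(const), np.full((3, 2, 2), 2.5))
    x = rng.permutation(64).reshape(1, 8, 8).astype(float)
    np.testing.assert_array_equal(maxpool2(x), maxpool_oracle(x))


def test_maxpool_rejects_odd():
    with pytest.raises(ValueError, match="even"):
        maxpool2(np.zeros((1, 3, 3)))


def test_maxpool_commutes_with_monotone_map(rng):
    x = rng.normal(size=(2, 6, 6))
    g = np.exp  # strictly increasing
    np.testing.assert_allclose(maxpool2(g(x)), g(maxpool2(x)), rtol=1e-12)


# --- bilinear upsampling ----------------------------------------------------


def test_upsample_hand_case():
    x = np.array([[[0.0, 2.0], [4.0, 6.0]]], np.float32)  # f(x, y) = 4x + 2y
    expected = np.array(
        [
            [0, 2 / 3, 4 / 3, 2],
            [4 / 3, 2, 8 / 3, 10 / 3],
            [8 / 3, 10 / 3, 4, 14 / 3],
            [4, 14 / 3, 16 / 3, 6],
        ]
    )
    np.testing.assert_allclose(upsample_bilinear(x, 4)[0], expected, atol=TOL)


@pytest.mark.parametrize("size_in,size_out", [(2, 4), (3, 7), (4, 8), (5, 6)])
def test_upsample_matches_loop_oracle(rng, size_in, size_out):
    x = rng.normal(size=(3, size_in, size_in)).astype(np.float32)
    np.testing.assert_allclose(
        upsample_bilinear(x, size_out), upsample_oracle(x, size_out), atol=TOL
    )


def test_upsample_identity_and_corners(rng):
    x = rng.normal(size=(2, 5, 5)).astype(np.float32)
    np.testing.assert_allclose(upsample_bilinear(x, 5), x, atol=TOL)
    up = upsample_bilinear(x, 11)
    for r, c in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
        np.testing.assert_allclose(up[:, r, c], x[:, r, c], atol=TOL)


def test_upsample_round_trip_preserves_lattice_points(rng):
    # doubling 3 -> 5 keeps the original samples on the even lattice
    x = rng.normal(size=(1, 3, 3)).astype(np.float32)
    up = upsample_bilinear(x, 5)
    np.testing.assert_allclose(up[:, ::2, ::2], x, atol=TOL)


def test_upsample_rejects_small_output():
    with pytest.raises(ValueError):
        upsample_bilinear(np.zeros((1, 2, 2), np.float32), 1)


# --- softmax ----------------------------------------------------------------


def test_softmax_cases(rng):
    uniform = softmax_pixelwise(np.zeros((3, 2, 2)))
    np.testing.assert_allclose(uniform, 1 / 3, atol=TOL)
    logits = rng.normal(size=(3, 4, 4))
    np.testing.assert_allclose(
        softmax_pixelwise(logits), softmax_pixelwise(logits + 5.0), atol=TOL
    )
    known = np.log(np.array([1.0, 2.0, 3.0]))[:, None, None] * np.ones((3, 2, 2))
    np.testing.assert_allclose(
        softmax_pixelwise(known), np.array([1 / 6, 2 / 6, 3 / 6])[:, None, None] * np.ones((3, 2, 2)), atol=TOL
    )
    sums = softmax_pixelwise(rng.normal(size=(3, 5, 5))).sum(axis=0)
    np.testing.assert_allclose(sums, 1.0, atol=TOL)


# --- forward ----------------------------------------------------------------


def test_forward_shape_and_zero_weight_uniformity(tiny_spec):
    weights = [
        ConvWeights(np.zeros((l.out_channels, l.in_channels, l.kernel, l.kernel), np.float32),
                    np.zeros(l.out_channels, np.float32))
        for l in tiny_spec.conv_layers
    ]
    img = np.random.default_rng(5).random((3, 64, 64)).astype(np.float32)
    probs = forward(tiny_spec, weights, img)
    assert probs.shape == (3, 64, 64)
    np.testing.assert_allclose(probs, 1 / 3, atol=TOL)
    assert (predict_labels(probs) == 0).all()  # ties break to lowest class


def test_forward_equals_operator_composition(tiny_spec, rng):
    """The graph executor must agree with manually chaining the operators."""
    weights = init_weights(tiny_spec, seed=11)
    img = rng.random((3, 64, 64)).astype(np.float32)
    logits = forward_logits(tiny_spec, weights, img)

    x = conv2d(img, weights[0])
    x = relu(x)
    skip = x
    x = maxpool2(x)
    x = relu(conv2d(x, weights[1]))
    x = upsample_bilinear(x, 64)
    x = np.concatenate([skip, x], axis=0)
    x = relu(conv2d(x, weights[2]))
    x = conv2d(x, weights[3])
    np.testing.assert_allclose(logits, x, atol=1e-5)


def test_forward_weight_mismatch_names_layer(tiny_spec, rng):
    weights = init_weights(tiny_spec, seed=1)
    weights[2] = ConvWeights(
        rng.normal(size=(4, 9, 3, 3)).astype(np.float32), np.zeros(4, np.float32)
    )
    with pytest.raises(ValueError, match="c3"):
        forward_logits(tiny_spec, weights, rng.random((3, 64, 64)).astype(np.float32))
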