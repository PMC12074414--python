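"""Training: loss, schedule, gradients, determinism, weight export."""

import numpy as np
import pytest

from crownseg.architecture import model_param_total
from crownseg.reference import ConvWeights, forward_logits
from crownseg.training import (
    InMemoryDataset,
    TrainConfig,
    _Engine,
    cross_entropy_loss,
    export_weights,
    init_weights,
    load_weights,
    lr_schedule,
    train,
)


def _blob_pair(rng, size=32, label=1):
    """A coloured-square-on-grey tile: trivially learnable segmentation."""
    img = np.full((3, size, size), 0.5, np.float32)
    img += rng.normal(0, 0.02, size=img.shape).astype(np.float32)
    mask = np.zeros((size, size), np.uint8)
    s = size // 2
    r, c = rng.integers(0, size - s, size=2)
    color = (0.1, 0.7, 0.2) if label == 1 else (0.8, 0.3, 0.1)
    img[:, r : r + s, c : c + s] = np.asarray(color, np.float32)[:, None, None]
    mask[r : r + s, c : c + s] = label
    return img, mask


@pytest.fixture
def blob_dataset(rng):
    pairs = [_blob_pair(rng, label=1 + i % 2) for i in range(12)]
    return InMemoryDataset(train=pairs[:8], val=pairs[8:])


# --- loss -------------------------------------------------------------------


def test_loss_uniform_logits_is_log3(rng):
    logits = np.zeros((3, 4, 4))
    target = rng.integers(0, 3, (4, 4))
    assert cross_entropy_loss(logits, target) == pytest.approx(np.log(3))


def test_loss_vanishes_for_confident_correct_prediction(rng):
    target = rng.integers(0, 3, (4, 4))
    logits = np.full((3, 4, 4), -50.0)
    np.put_along_axis(logits, target[None], 50.0, axis=0)
    assert cross_entropy_loss(logits, target) < 1e-8
    assert cross_entropy_loss(logits * 0 + 1.0, target) > 0  # never negative/zero otherwise


def test_loss_two_pixel_closed_form():
    # pixel A: logits (1, 0, 0) target 0; pixel B: logits (0, 2, 0) target 2
    logits = np.array([[[1.0, 0.0]], [[0.0, 2.0]], [[0.0, 0.0]]])
    target = np.array([[0, 2]])
    z_a = np.exp(1) + 2
    z_b = 2 + np.exp(2)
    expected = (np.log(z_a) - 1 + np.log(z_b) - 0) / 2
    assert cross_entropy_loss(logits, target) == pytest.approx(expected)


def test_loss_rejects_bad_labels():
    with pytest.raises(ValueError, match="labels"):
        cross_entropy_loss(np.zeros((3, 2, 2)), np.full((2, 2), 5))


# --- schedule ---------------------------------------------------------------


def test_cosine_schedule_endpoints_and_midpoint():
    cfg = TrainConfig(iterations=1001)
    assert lr_schedule(0, cfg) == pytest.approx(1e-4)
    assert lr_schedule(1000, cfg) == pytest.approx(1e-6)
    assert lr_schedule(500, cfg) == pytest.approx((1e-4 + 1e-6) / 2)


@pytest.mark.parametrize("schedule", ["cosine", "step"])
def test_schedule_monotone_nonincreasing(schedule):
    cfg = TrainConfig(iterations=200, schedule=schedule)
    rates = [lr_schedule(i, cfg) for i in range(200)]
    assert all(a >= b for a, b in zip(rates, rates[1:]))
    assert rates[0] == cfg.lr_max and rates[-1] >= cfg.lr_min


# --- gradients --------------------------------------------------------------


def test_gradients_match_finite_differences(tiny_spec, rng):
    engine = _Engine(tiny_spec)
    weights = init_weights(tiny_spec, seed=3)
    img = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
    mask = rng.integers(0, 3, size=(2, 8, 8))

    logits, cache, _ = engine.forward(weights, img, keep_cache=True)
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, mask[:, None].astype(np.int64), 1.0, axis=1)
    grads = engine.backward(weights, cache, ((probs - onehot) / mask.size).astype(np.float32))

    def loss_at(ws):
        lg, _, _ = engine.forward(ws, img, keep_cache=False)
        return cross_entropy_loss(lg, mask)

    rng2 = np.random.default_rng(0)
    checked = 0
    for li in range(len(weights)):
        for which in ("kernels", "bias"):
            arr = getattr(weights[li], which)
            idx = tuple(rng2.integers(0, s) for s in arr.shape)
            eps = 1e-3
            ws = [ConvWeights(w.kernels.copy(), w.bias.copy()) for w in weights]
            getattr(ws[li], which)[idx] += eps
            lp = loss_at(ws)
            getattr(ws[li], which)[idx] -= 2 * eps
            lm = loss_at(ws)
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[li][0 if which == "kernels" else 1][idx]
            assert analytic == pytest.approx(numeric, rel=1e-2, abs=1e-5)
            checked += 1
    assert checked == 8


def test_batched_forward_matches_reference_engine(tiny_spec, rng):
    weights = init_weights(tiny_spec, seed=5)
    img = rng.random((3, 64, 64)).astype(np.float32)
    batched, _, _ = _Engine(tiny_spec).forward(weights, img[None], keep_cache=False)
    single = forward_logits(tiny_spec, weights, img)
    np.testing.assert_allclose(batched[0], single, atol=1e-5)


# --- end-to-end training ----------------------------------------------------


def test_training_is_seed_deterministic(tiny_spec, blob_dataset):
    cfg = TrainConfig(image_size=32, iterations=12, eval_interval=6, seed=21)
    w1, h1 = train(tiny_spec, blob_dataset, cfg)
    w2, h2 = train(tiny_spec, blob_dataset, cfg)
    assert h1.train_loss == h2.train_loss
    assert h1.val_miou == h2.val_miou
    for a, b in zip(w1, w2):
        np.testing.assert_array_equal(a.kernels, b.kernels)


def test_training_learns_blob_segmentation(tiny_spec, blob_dataset):
    cfg = TrainConfig(image_size=32, iterations=120, eval_interval=40, seed=2,
                      lr_max=3e-3, lr_min=1e-4)
    weights, history = train(tiny_spec, blob_dataset, cfg)
    assert history.val_loss[-1] < history.val_loss[0]
    assert history.best_val_miou > 0.5


def test_empty_split_raises(tiny_spec):
    ds = InMemoryDataset(train=[], val=[])
    with pytest.raises(ValueError, match="train"):
        train(tiny_spec, ds, TrainConfig(iterations=1))


def test_epoch_iteration_unit_scales_steps(tiny_spec, blob_dataset):
    cfg = TrainConfig(iterations=2, iteration_unit="epoch", batch_size=2,
                      eval_interval=100, seed=0)
    _, history = train(tiny_spec, blob_dataset, cfg)
    assert len(history.steps) == 2 * 4  # 8 train tiles / batch 2 = 4 steps/epoch


# --- export -----------------------------------------------------------------


def test_sidecar_round_trip_bit_exact(tiny_spec, tmp_path, rng):
    weights = init_weights(tiny_spec, seed=7)
    path = export_weights(tiny_spec, weights, tmp_path / "w.bin")
    loaded = load_weights(path, tiny_spec)
    for a, b in zip(weights, loaded):
        np.testing.assert_array_equal(a.kernels, b.kernels)
        np.testing.assert_array_equal(a.bias, b.bias)
    img = rng.random((3, 64, 64)).astype(np.float32)
    np.testing.assert_array_equal(
        forward_logits(tiny_spec, weights, img), forward_logits(tiny_spec, loaded, img)
    )


def test_sidecar_payload_size_is_four_bytes_per_parameter(tiny_spec, tmp_path):
    weights = init_weights(tiny_spec, seed=1)
    path = export_weights(tiny_spec, weights, tmp_path / "w.bin")
    n_params = model_param_total(tiny_spec)
    overhead = len(b"CSWT\x01") + 4 + sum(
        2 + len(l.name.encode()) + 16 + 4 for l in tiny_spec.conv_layers
    )
    assert path.stat().st_size == overhead + 4 * n_params


def test_export_tensor_pair_count_matches_conv_census(tmp_path):
    from crownseg.architecture import build_unet_light

    spec = build_unet_light()
    weights = init_weights(spec, seed=0)
    path = export_weights(spec, weights, tmp_path / "light.bin")
    loaded = load_weights(path)
    assert len(loaded) == 22  # one kernel/bias pair per convolution


def test_export_shape_mismatch_raises(tiny_spec, tmp_path):
    weights = init_weights(tiny_spec, seed=0)
    weights[0] = ConvWeights(np.zeros((4, 3, 1, 1), np.float32), np.zeros(4, np.float32))
    with pytest.raises(ValueError, match="c1"):
        export_weights(tiny_spec, weights, tmp_path / "bad.bin")
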