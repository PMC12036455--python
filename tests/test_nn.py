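"""Network blocks: shape contracts, parameter budgets, gradients, training."""

import numpy as np
import pytest

from hodgeimage.nn import (
    BatchNormNd,
    ConvNd,
    FeedForwardConv,
    Linear,
    MaxPoolHalf,
    ModelConfig,
    MultiHeadConv,
    ReLU,
    TrainConfig,
    TransConvLayer,
    build_model,
    count_params,
    cross_entropy_loss,
    bce_with_logits_loss,
    evaluate,
    load_model,
    save_model,
    train,
)
from hodgeimage.nn.model import Network
from hodgeimage.nn.train import one_cycle_lr, predict_logits


def seq_params(module):
    return module.parameters()


def numeric_grad(fn, arr, idx, eps=1e-2):
    orig = arr[idx]
    arr[idx] = orig + eps
    lp = fn()
    arr[idx] = orig - eps
    lm = fn()
    arr[idx] = orig
    return (lp - lm) / (2 * eps)


# ---------------------------------------------------------------- shapes

def test_multi_head_conv_preserves_spatial_dims(rng):
    block = MultiHeadConv(2, 72, 4, rng)
    x = rng.standard_normal((2, 72, 32, 32)).astype(np.float32)
    assert block.forward(x, training=True).shape == (2, 72, 32, 32)


def test_feed_forward_conv_channel_trace(rng):
    block = FeedForwardConv(2, 72, 3, rng)
    x = rng.standard_normal((1, 72, 8, 8)).astype(np.float32)
    inner = block.modules[0].forward(x, training=True)
    assert inner.shape == (1, 144, 8, 8)  # C -> 2C
    assert block.forward(x, training=True).shape == (1, 72, 8, 8)


def test_trans_conv_layer_halves_spatial_dims(rng):
    layer = TransConvLayer(2, 72, 4, 3, rng)
    x = rng.standard_normal((2, 72, 32, 32)).astype(np.float32)
    assert layer.forward(x, training=True).shape == (2, 72, 16, 16)
    layer3 = TransConvLayer(3, 64, 4, 1, rng)
    x3 = rng.standard_normal((1, 64, 16, 16, 16)).astype(np.float32)
    assert layer3.forward(x3, training=True).shape == (1, 64, 8, 8, 8)


def test_five_layers_reduce_224_to_7(rng):
    x = np.zeros((1, 72, 224, 224), np.float32)
    for _ in range(5):
        x = MaxPoolHalf(2).forward(x, training=False)
    assert x.shape[2:] == (7, 7)


def test_odd_extent_rejected_by_pool():
    with pytest.raises(ValueError):
        MaxPoolHalf(2).forward(np.zeros((1, 4, 5, 6), np.float32), training=False)


def test_forward_pads_to_pool_multiple():
    cfg = ModelConfig(2, 6, 24, 2, 2, 3, 2)
    model = build_model(cfg, seed=0)
    logits = model.forward(np.zeros((2, 6, 31, 31), np.float32))
    assert logits.shape == (2, 2)
    assert np.all(np.isfinite(logits))


# ------------------------------------------------------- parameter counts

def conv_param_count(cin, cout, k, g, ndim):
    return cout * (cin // g) * k**ndim + cout


def test_multi_head_conv_closed_form_count(rng):
    block = MultiHeadConv(2, 72, 4, rng)
    expected = conv_param_count(72, 288, 3, 4, 2) + conv_param_count(288, 72, 1, 1, 2)
    assert expected == 67752
    assert sum(p.value.size for p in block.parameters()) == expected


def test_feed_forward_conv_closed_form_count(rng):
    block = FeedForwardConv(2, 72, 3, rng)
    expected = conv_param_count(72, 144, 1, 3, 2) + conv_param_count(144, 72, 1, 3, 2)
    assert expected == 7128
    assert sum(p.value.size for p in block.parameters()) == expected


def analytic_total(cfg: ModelConfig) -> int:
    nd, c = cfg.ndim, cfg.hidden_channels
    total = conv_param_count(cfg.in_channels, c, 3, 1, nd) + 2 * c  # init conv + BN
    per_layer = (
        conv_param_count(c, c * cfg.heads, 3, cfg.heads, nd)
        + conv_param_count(c * cfg.heads, c, 1, 1, nd)
        + 2 * c  # BN after MultiHeadConv residual
        + conv_param_count(c, 2 * c, 1, cfg.groups, nd)
        + conv_param_count(2 * c, c, 1, cfg.groups, nd)
        + 2 * c  # BN after FeedForwardConv residual
    )
    total += cfg.n_layers * per_layer
    total += c * c + c  # MLP hidden
    total += c * cfg.n_classes + cfg.n_classes
    return total


@pytest.mark.parametrize(
    "cfg, budget",
    [
        (ModelConfig(2, 6, 72, 4, 3, 5, 9), 0.56e6),
        (ModelConfig(3, 9, 64, 4, 1, 5, 11), 0.75e6),
    ],
)
def test_reference_configs_fit_parameter_budgets(cfg, budget):
    model = build_model(cfg, seed=0)
    n = count_params(model)
    assert n == analytic_total(cfg)
    assert n <= budget


def test_config_divisibility_validation():
    with pytest.raises(ValueError):
        ModelConfig(2, 6, 70, 4, 3, 5, 9)  # 70 % 4 != 0
    with pytest.raises(ValueError):
        ModelConfig(2, 6, 72, 4, 5, 5, 9)  # 72 % 5 != 0
    with pytest.raises(ValueError):
        ModelConfig(4, 6, 72, 4, 3, 5, 9)


# ------------------------------------------------------------- gradients

def test_conv_gradients_match_finite_differences(rng):
    for ndim, k, g in [(2, 3, 2), (2, 1, 3), (3, 3, 1)]:
        conv = ConvNd(ndim, 6, 6, kernel_size=k, groups=g, rng=rng)
        x = rng.standard_normal((2, 6) + (5,) * ndim).astype(np.float32)
        t = rng.standard_normal((2, 6) + (5,) * ndim).astype(np.float32)

        def loss():
            out = conv.forward(x, training=True)
            return float(np.sum((out - t) ** 2))

        out = conv.forward(x, training=True)
        conv.w.grad[...] = 0
        conv.b.grad[...] = 0
        dx = conv.backward(2 * (out - t))
        for p in (conv.w, conv.b):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            num = numeric_grad(loss, p.value, idx)
            assert abs(num - p.grad[idx]) < 2e-2 * max(abs(num), 1.0)
        idx = (1, 3) + (2,) * ndim
        num = numeric_grad(loss, x, idx)
        assert abs(num - dx[idx]) < 2e-2 * max(abs(num), 1.0)


def test_batchnorm_gradients_match_finite_differences(rng):
    bn = BatchNormNd(4, 2)
    x = rng.standard_normal((8, 4, 3, 3)).astype(np.float32)
    t = rng.standard_normal((8, 4, 3, 3)).astype(np.float32)

    def loss():
        return float(np.sum((bn.forward(x, training=True) - t) ** 2))

    out = bn.forward(x, training=True)
    bn.gamma.grad[...] = 0
    bn.beta.grad[...] = 0
    dx = bn.backward(2 * (out - t))
    for p in (bn.gamma, bn.beta):
        num = numeric_grad(loss, p.value, (1,))
        assert abs(num - p.grad[1]) < 2e-2 * max(abs(num), 1.0)
    idx = (3, 1, 2, 0)
    num = numeric_grad(loss, x, idx)
    assert abs(num - dx[idx]) < 2e-2 * max(abs(num), 1.0)


def test_full_network_input_gradient(rng):
    cfg = ModelConfig(2, 3, 8, 2, 2, 1, 4)
    net = build_model(cfg, seed=3)
    X = rng.standard_normal((4, 3, 4, 4)).astype(np.float32)
    y = np.array([0, 1, 2, 3])

    def loss():
        return cross_entropy_loss(net.forward(X, training=True), y)[0]

    _, dlog = cross_entropy_loss(net.forward(X, training=True), y)
    for p in net.parameters():
        p.grad[...] = 0
    dX = net.backward(dlog)
    idx = (1, 2, 1, 3)
    num = numeric_grad(loss, X, idx, eps=1e-3)
    assert abs(num - dX[idx]) < 5e-2 * max(abs(num), 1e-3)


def test_gradient_flows_to_every_block(rng):
    """Every weight and batch-norm affine parameter receives gradient.

    Convolution biases directly feeding a batch norm legitimately have
    zero gradient (the norm subtracts the mean), so they are exempt.
    """
    cfg = ModelConfig(2, 3, 8, 2, 2, 2, 3)
    net = build_model(cfg, seed=1)
    X = rng.standard_normal((6, 3, 8, 8)).astype(np.float32)
    y = np.array([0, 1, 2, 0, 1, 2])
    logits = net.forward(X, training=True)
    _, dlog = cross_entropy_loss(logits, y)
    for p in net.parameters():
        p.grad[...] = 0
    net.backward(dlog)
    from hodgeimage.nn.model import _walk

    for mod in _walk(net.body):
        if isinstance(mod, ConvNd):
            assert np.abs(mod.w.grad).max() > 0
        elif isinstance(mod, BatchNormNd):
            assert np.abs(mod.gamma.grad).max() > 0
            assert np.abs(mod.beta.grad).max() > 0
        elif isinstance(mod, Linear):
            assert np.abs(mod.w.grad).max() > 0
            assert np.abs(mod.b.grad).max() > 0


def test_zero_input_zero_bias_gives_zero_conv_output(rng):
    conv = ConvNd(2, 4, 8, kernel_size=3, groups=2, rng=rng)
    conv.b.value[...] = 0
    out = conv.forward(np.zeros((1, 4, 6, 6), np.float32), training=False)
    assert np.abs(out).max() == 0.0


# ------------------------------------------------------------ losses / lr

def test_initial_loss_is_log_num_classes(rng):
    """Uniform logits on balanced labels give ln(K)."""
    logits = np.zeros((12, 4))
    y = np.tile(np.arange(4), 3)
    loss, dlog = cross_entropy_loss(logits, y)
    assert abs(loss - np.log(4)) < 1e-12
    assert dlog.shape == (12, 4)


def test_bce_with_logits_matches_reference(rng):
    logits = rng.standard_normal((5, 3))
    targets = (rng.random((5, 3)) > 0.5).astype(float)
    loss, grad = bce_with_logits_loss(logits, targets)
    sig = 1 / (1 + np.exp(-logits))
    ref = -np.mean(targets * np.log(sig) + (1 - targets) * np.log(1 - sig))
    assert abs(loss - ref) < 1e-10
    num = numeric_grad(
        lambda: bce_with_logits_loss(logits, targets)[0], logits, (2, 1), eps=1e-5
    )
    assert abs(num - grad[2, 1]) < 1e-5


def test_untrained_model_auc_near_half(rng):
    cfg = ModelConfig(2, 2, 8, 2, 2, 1, 2)
    net = build_model(cfg, seed=0)
    X = rng.standard_normal((200, 2, 8, 8)).astype(np.float32)
    y = np.tile([0, 1], 100)
    rep = evaluate(net, X, y)
    assert 0.3 < rep["auc"] < 0.7


def test_one_cycle_schedule_shape():
    total = 100
    lrs = [one_cycle_lr(s, total, 1e-3) for s in range(total)]
    peak = int(np.argmax(lrs))
    assert abs(peak - 30) <= 1
    assert max(lrs) <= 1e-3 + 1e-12
    assert lrs[0] == pytest.approx(1e-3 / 25)
    assert lrs[-1] < 1e-5


# -------------------------------------------------------------- training

def small_problem(rng, n=24):
    """Linearly separable two-class blobs as channel images."""
    X = rng.standard_normal((n, 2, 8, 8)).astype(np.float32) * 0.2
    y = np.tile([0, 1], n // 2)
    X[y == 1, 0] += 1.0
    return X, y


def test_training_is_bit_reproducible(rng):
    X, y = small_problem(rng)
    cfg = ModelConfig(2, 2, 8, 2, 2, 1, 2)
    tc = TrainConfig(epochs=2, batch_size=8, seed=11)
    m1 = build_model(cfg, seed=5)
    h1 = train(m1, X, y, tc)
    m2 = build_model(cfg, seed=5)
    h2 = train(m2, X, y, tc)
    assert h1 == h2
    for p1, p2 in zip(m1.parameters(), m2.parameters()):
        assert np.array_equal(p1.value, p2.value)


def test_training_reduces_loss_and_logs_metrics(rng):
    X, y = small_problem(rng, n=32)
    cfg = ModelConfig(2, 2, 8, 2, 2, 1, 2)
    model = build_model(cfg, seed=2)
    history = train(model, X, y, TrainConfig(epochs=8, batch_size=8, seed=0),
                    X_val=X[:8], y_val=y[:8])
    train_recs = [r for r in history if r["split"] == "train"]
    assert {"epoch", "split", "loss", "acc", "auc"} <= set(train_recs[0])
    assert train_recs[-1]["loss"] < train_recs[0]["loss"]
    assert any(r["split"] == "val" for r in history)


def test_label_loss_mismatch_raises(rng):
    X, y = small_problem(rng)
    cfg = ModelConfig(2, 2, 8, 2, 2, 1, 2, loss="bce_with_logits")
    model = build_model(cfg, seed=0)
    with pytest.raises(ValueError):
        train(model, X, y, TrainConfig(epochs=1, batch_size=8))


def test_checkpoint_roundtrip(tmp_path, rng):
    X, y = small_problem(rng)
    cfg = ModelConfig(2, 2, 8, 2, 2, 1, 2)
    model = build_model(cfg, seed=4)
    train(model, X, y, TrainConfig(epochs=1, batch_size=8, seed=0))
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert np.array_equal(predict_logits(back, X), predict_logits(model, X))
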