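"""The hybrid classifier: layer gradients, architecture contracts,
attention-gate behavior and training mechanics."""

import numpy as np
import pytest

from lungcyto.errors import ConfigurationError, DataError
from lungcyto.nn import (Adam, AttentionGate, ModelConfig, build_attention_branch,
                         build_hybrid, build_residual_branch, conv_layer_count,
                         desk_config, head_param_count, predict, softmax,
                         softmax_cross_entropy, train_model)

MICRO = ModelConfig(input_size=(16, 16), resnet_plan=(1, 1), unet_depth=2,
                    base_filters=2, branch_dropout=0.0, head_dropout=0.0,
                    head_units=8, num_classes=3, seed=0, batch_size=3,
                    epochs=2, learning_rate=1e-3)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(num_classes=1)
    with pytest.raises(ConfigurationError):
        ModelConfig(input_size=(24, 24), unet_depth=4)  # 24 % 16 != 0


def test_canonical_50_layer_plan():
    assert conv_layer_count((3, 4, 6, 3)) == 50
    assert conv_layer_count((3, 4, 6, 3), include_classifier=False) == 49


def test_branch_feature_lengths_and_shapes(rng):
    res = build_residual_branch(MICRO)
    att = build_attention_branch(MICRO)
    x = rng.random((2, 1, 16, 16))
    f1 = res.forward(x, train=False)
    f2 = att.forward(x, train=False)
    assert f1.shape == (2, res.feature_len)
    assert f2.shape == (2, att.feature_len)
    # bottleneck expansion: last stage outputs 4 * base * 2**(stages-1)
    assert res.feature_len == 4 * MICRO.base_filters * 2 ** (len(MICRO.resnet_plan) - 1)
    assert att.n_gates == MICRO.unet_depth
    assert len(att.enc) == len(att.dec)  # symmetric encoder/decoder


def test_residual_block_identity_with_zeroed_convs(rng):
    from lungcyto.nn import Bottleneck, Conv2D
    blk = Bottleneck(4, 2, 4, stride=1, rng=np.random.default_rng(0))
    for layer in blk.main.layers:
        if isinstance(layer, Conv2D):
            layer.w[...] = 0.0
            layer.b[...] = 0.0
    x = np.abs(rng.random((2, 4, 8, 8)))
    out = blk.forward(x, train=False)
    assert np.allclose(out, x)  # relu(0 + x) = x for x >= 0


def test_attention_gate_limits_and_range(rng):
    gate = AttentionGate(cx=3, cg=5, cint=2, rng=np.random.default_rng(0))
    x = rng.random((2, 3, 8, 8))
    g = rng.random((2, 5, 8, 8))
    out = gate.forward(x, g, train=False)
    assert out.shape == x.shape
    assert np.all(gate.last_alpha > 0) and np.all(gate.last_alpha < 1)
    # forcing psi to a large negative bias suppresses everything
    gate.psi.w[...] = 0.0
    gate.psi.b[...] = -50.0
    assert np.allclose(gate.forward(x, g, train=False), 0.0, atol=1e-12)
    # large positive bias passes x through
    gate.psi.b[...] = 50.0
    assert np.allclose(gate.forward(x, g, train=False), x, atol=1e-6)


def test_hybrid_gradients_match_numerics(rng):
    model = build_hybrid(MICRO)
    x = rng.random((3, 1, 16, 16))
    y = np.array([0, 1, 2])

    def loss():
        return softmax_cross_entropy(model.forward(x, train=True), y)[0]

    model.zero_grad()
    _, dl = softmax_cross_entropy(model.forward(x, train=True), y)
    model.backward(dl)
    params = model.parameters()
    eps = 1e-6
    for pi in rng.choice(len(params), size=15, replace=False):
        p = params[pi]
        flat = p["value"].ravel()
        for k in rng.choice(flat.size, size=min(2, flat.size), replace=False):
            orig = flat[k]
            flat[k] = orig + eps
            lp = loss()
            flat[k] = orig - eps
            lm = loss()
            flat[k] = orig
            num = (lp - lm) / (2 * eps)
            ana = p["grad"].ravel()[k]
            assert ana == pytest.approx(num, abs=1e-5, rel=1e-4), p["name"]


def test_softmax_validity_on_random_logits(rng):
    logits = rng.normal(0, 10, (1000, 3))
    p = softmax(logits)
    assert np.all(p >= 0)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    # uniform logits give uniform probabilities
    assert np.allclose(softmax(np.ones((4, 3))), 1 / 3)


def test_hybrid_outputs_are_probabilities(rng):
    model = build_hybrid(MICRO)
    imgs = [(rng.random((16, 16)) * 255).astype(np.uint8) for _ in range(4)]
    probs, labels = predict(model, imgs)
    assert probs.shape == (4, 3)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert all(l in model.class_names for l in labels)
    # duplicated input rows give identical outputs
    probs2, _ = predict(model, [imgs[0], imgs[0]])
    assert np.allclose(probs2[0], probs2[1])


def test_fused_length_and_head_param_arithmetic():
    model = build_hybrid(MICRO)
    assert model.fused_len == (model.residual.feature_len
                               + model.attention.feature_len)
    u = MICRO.head_units
    expected = (model.fused_len + 1) * u + 2 * u + (u + 1) * MICRO.num_classes
    assert head_param_count(model) == expected


def test_zero_learning_rate_is_null_update(rng):
    model = build_hybrid(MICRO)
    cfg = ModelConfig(**{**MICRO.__dict__, "learning_rate": 0.0, "epochs": 1})
    before = model.get_weights()
    imgs = [(rng.random((16, 16)) * 255).astype(np.uint8) for _ in range(6)]
    train_model(model, imgs, ["adenocarcinoma", "neuroendocrine", "squamous"] * 2,
                cfg, restore_best=False)
    after = model.get_weights()
    assert all(np.allclose(b, a, atol=1e-12) for b, a in zip(before, after))


def test_single_step_decreases_loss(rng):
    """Gradient flow: one Adam step at a healthy lr lowers the batch
    loss for a fresh model (three seeds tried for stochastic safety)."""
    for seed in range(3):
        cfg = ModelConfig(**{**MICRO.__dict__, "seed": seed})
        model = build_hybrid(cfg)
        x = np.random.default_rng(seed).random((6, 1, 16, 16))
        y = np.array([0, 1, 2, 0, 1, 2])
        model.zero_grad()
        loss0, dl = softmax_cross_entropy(model.forward(x, train=True), y)
        model.backward(dl)
        Adam(model.parameters(), lr=1e-3).step()
        loss1, _ = softmax_cross_entropy(model.forward(x, train=False), y)
        if loss1 < loss0:
            return
    pytest.fail("loss did not decrease for any of three seeds")


def test_history_length_and_reproducibility(rng):
    imgs = [(rng.random((16, 16)) * 255).astype(np.uint8) for _ in range(6)]
    labels = ["adenocarcinoma", "neuroendocrine", "squamous"] * 2
    h1 = train_model(build_hybrid(MICRO), imgs, labels, MICRO,
                     restore_best=False)
    h2 = train_model(build_hybrid(MICRO), imgs, labels, MICRO,
                     restore_best=False)
    assert len(h1.train_loss) == MICRO.epochs
    assert len(h1.val_accuracy) == MICRO.epochs
    assert h1.train_loss == h2.train_loss  # bitwise-identical training


def test_empty_training_set_rejected():
    with pytest.raises(DataError):
        train_model(build_hybrid(MICRO), [], [], MICRO)
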