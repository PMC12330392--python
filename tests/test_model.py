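"""MIL model math: attention pooling, baselines, encoder contracts, persistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sonomil as sm
from sonomil.errors import CapabilityError, ConfigurationError, EmptyBagError
from sonomil.model import AttentionParams, _stack_bag, build_encoder

RNG = np.random.default_rng(7)


def random_params(rng, dim=8, hidden=4):
    return AttentionParams(W1=rng.normal(size=(dim, hidden)),
                           b1=rng.normal(size=hidden),
                           W2=rng.normal(size=(hidden, 1)),
                           b2=float(rng.normal()))


def scalar_loop_attention(H, p):
    """Independent per-instance reference: explicit Python loops, no matmul."""
    import math
    n, d = H.shape
    hidden = p.W1.shape[1]
    scores = []
    for i in range(n):
        s = p.b2
        for k in range(hidden):
            z = p.b1[k]
            for j in range(d):
                z += H[i, j] * p.W1[j, k]
            s += math.tanh(z) * p.W2[k, 0]
        scores.append(s)
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    total = sum(exps)
    a = [e / total for e in exps]
    M = [sum(a[i] * H[i, j] for i in range(n)) for j in range(d)]
    return np.array(a), np.array(M)


def test_attention_single_instance_and_identical_instances():
    p = random_params(RNG)
    h = RNG.normal(size=(1, 8))
    weights, M = sm.attention_pool(h, p)
    np.testing.assert_allclose(weights.a, [1.0])
    np.testing.assert_allclose(M, h[0])
    H = np.repeat(RNG.normal(size=(1, 8)), 5, axis=0)
    weights, M = sm.attention_pool(H, p)
    np.testing.assert_allclose(weights.a, np.full(5, 0.2), atol=1e-12)
    np.testing.assert_allclose(M, H[0], atol=1e-12)


def test_attention_with_zero_w2_is_mean_pooling():
    p = random_params(RNG)
    p.W2 = np.zeros_like(p.W2)
    H = RNG.normal(size=(7, 8))
    weights, M = sm.attention_pool(H, p)
    np.testing.assert_allclose(weights.a, np.full(7, 1 / 7))
    np.testing.assert_allclose(M, sm.mean_pool(H), atol=1e-12)


def test_attention_matches_scalar_loop_oracle():
    for trial in range(20):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(1, 8))
        H = rng.normal(scale=2.0, size=(n, 8))
        p = random_params(rng)
        weights, M = sm.attention_pool(H, p)
        a_ref, m_ref = scalar_loop_attention(H, p)
        np.testing.assert_allclose(weights.a, a_ref, atol=1e-6)
        np.testing.assert_allclose(M, m_ref, atol=1e-6)


def test_attention_rejects_empty_or_nonfinite_bags():
    p = random_params(RNG)
    with pytest.raises(EmptyBagError):
        sm.attention_pool(np.empty((0, 8)), p)
    with pytest.raises(ValueError):
        sm.attention_pool(np.full((2, 8), np.nan), p)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=2**31 - 1))
def test_attention_weights_are_a_distribution_for_any_input(n, seed):
    rng = np.random.default_rng(seed)
    H = rng.normal(scale=10.0 ** rng.integers(-2, 3), size=(n, 8))
    weights, _ = sm.attention_pool(H, random_params(rng))
    assert np.all(weights.a > 0)
    assert abs(weights.a.sum() - 1.0) < 1e-6


def test_max_and_mean_pool_against_loop_oracle():
    h1 = np.zeros(512); h1[0] = 1.0
    h2 = np.zeros(512); h2[1] = 1.0
    H = np.stack([h1, h2])
    expected_max = np.zeros(512); expected_max[:2] = 1.0
    np.testing.assert_array_equal(sm.max_pool(H), expected_max)
    np.testing.assert_array_equal(sm.mean_pool(H), expected_max / 2)
    H = RNG.normal(size=(5, 16))
    loop_max = np.array([max(H[i, j] for i in range(5)) for j in range(16)])
    loop_mean = np.array([sum(H[i, j] for i in range(5)) / 5 for j in range(16)])
    np.testing.assert_allclose(sm.max_pool(H), loop_max)
    np.testing.assert_allclose(sm.mean_pool(H), loop_mean)
    assert len(sm.max_pool(H[:1])) == 16
    with pytest.raises(EmptyBagError):
        sm.max_pool(np.empty((0, 4)))


def test_classify_bag_sigmoid_head():
    M = RNG.normal(size=16)
    pred = sm.classify_bag(M, np.zeros(16), 0.0)
    assert pred.probability == 0.5
    w = RNG.normal(size=16)
    expected_logit = sum(float(M[i]) * float(w[i]) for i in range(16)) + 0.3
    pred = sm.classify_bag(M, w, 0.3)
    assert abs(pred.logits - expected_logit) < 1e-9
    assert abs(pred.probability - 1 / (1 + np.exp(-expected_logit))) < 1e-7
    big = sm.classify_bag(M, w * 100, 500.0)
    assert big.probability > sm.classify_bag(M, w, 0.3).probability


@pytest.mark.parametrize("n,size", [(1, 32), (5, 32), (3, 64), (2, 16)])
def test_encoder_shape_contract_any_bag_size_and_resolution(n, size):
    encoder = build_encoder(sm.EncoderSpec(), np.random.default_rng(0))
    bag = [RNG.normal(size=(size, size)).astype(np.float32)] * n
    H = sm.encode_instances(bag, encoder=encoder)
    assert H.shape == (n, 512)
    assert np.all(np.isfinite(H))
    # duplicated images give identical feature rows
    np.testing.assert_array_equal(H[0], H[-1])


def test_encoder_matches_independent_scipy_convolution_oracle():
    """Forward pass equals an independent re-implementation of the same
    architecture built on scipy.ndimage.correlate."""
    from scipy.ndimage import correlate

    encoder = build_encoder(sm.EncoderSpec(pool="avg"), np.random.default_rng(5))
    img = RNG.normal(size=(16, 16)).astype(np.float32)
    H = sm.encode_instances([img], encoder=encoder)

    def conv_ref(x, layer, stride=1):  # x: (C,H,W)
        w, b = layer.weight.data, layer.bias.data
        pad = layer.padding
        out = []
        for o in range(w.shape[0]):
            acc = np.zeros(x.shape[1:])
            for c in range(x.shape[0]):
                acc += correlate(x[c].astype(np.float64), w[o, c].astype(np.float64),
                                 mode="constant")
            out.append(acc + b[o])
        out = np.stack(out)
        if pad == 0:  # trim the border correlate kept
            k = w.shape[-1]
            if k > 1:
                t = (k - 1) // 2
                out = out[:, t:-t, t:-t]
        return out[:, ::stride, ::stride]

    x = img[None].astype(np.float64)
    h = np.maximum(conv_ref(x, encoder.conv1, stride=2), 0)
    for layer in (encoder.conv2, encoder.conv3):
        h = np.maximum(conv_ref(h, layer), 0)
        h = np.maximum.reduce([h[:, 0::2, 0::2], h[:, 0::2, 1::2],
                               h[:, 1::2, 0::2], h[:, 1::2, 1::2]])
    proj = encoder.proj
    act = np.maximum(np.tensordot(proj.weight.data[:, :, 0, 0].astype(np.float64),
                                  h, axes=1)
                     + proj.bias.data[:, None, None], 0)
    np.testing.assert_allclose(H[0], act.mean(axis=(1, 2)), atol=1e-4)


def test_vgg13_backbone_reports_capability_error_suggesting_tinycnn():
    with pytest.raises(CapabilityError, match="tinycnn"):
        build_encoder(sm.EncoderSpec(backbone="vgg13", pretrained=True),
                      np.random.default_rng(0))
    with pytest.raises(ConfigurationError):
        sm.EncoderSpec(backbone="resnet")
    with pytest.raises(ConfigurationError):
        sm.EncoderSpec(pretrained=True)  # tinycnn has no pretrained weights


@pytest.mark.parametrize("pooling", ["attention", "max", "mean"])
def test_predict_is_invariant_to_instance_order(pooling):
    model = sm.MILModel(pooling=pooling, seed=2)
    bag = [RNG.normal(size=(32, 32)).astype(np.float32) for _ in range(6)]
    base = model.predict(bag)
    rng = np.random.default_rng(0)
    for _ in range(5):
        perm = rng.permutation(6)
        shuffled = model.predict([bag[i] for i in perm])
        assert abs(shuffled.probability - base.probability) < 1e-6
        if pooling == "attention":
            np.testing.assert_allclose(shuffled.attention.a, base.attention.a[perm],
                                       atol=1e-6)


def test_module_attention_equals_functional_form():
    model = sm.MILModel(seed=4)
    bag = [RNG.normal(size=(32, 32)).astype(np.float32) for _ in range(4)]
    out = model.forward(_stack_bag(bag))
    H = np.asarray(out["features"].data, dtype=np.float64)
    weights, M = sm.attention_pool(H, model.attention.params())
    np.testing.assert_allclose(np.asarray(out["attention"].data), weights.a, atol=1e-6)
    np.testing.assert_allclose(np.asarray(out["pooled"].data), M, atol=1e-5)
    pred = sm.classify_bag(M, model.head.W.data[:, 0], float(model.head.b.data[0]),
                           attention=weights)
    assert abs(pred.probability - float(out["prob"].data)) < 1e-6


def test_checkpoint_round_trip_preserves_predictions(tmp_path):
    model = sm.MILModel(pooling="attention", seed=9)
    bag = [RNG.normal(size=(32, 32)).astype(np.float32) for _ in range(3)]
    before = model.predict(bag)
    path = sm.save_checkpoint(model, tmp_path / "ckpt.npz", extra={"note": "test"})
    restored, extra = sm.load_checkpoint(path)
    assert extra["note"] == "test"
    after = restored.predict(bag)
    assert before.probability == after.probability
    np.testing.assert_array_equal(before.attention.a, after.attention.a)
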