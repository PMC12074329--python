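"""The patch transformer: normalisation, patching, attention, pooling, forward."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctgformer.autodiff import Tensor
from ctgformer.exceptions import (
    CTGError,
    DegenerateChannelError,
    DegenerateWindowError,
    ParameterError,
)
from ctgformer.model import (
    EncoderLayer,
    ModelConfig,
    PatchTransformerNet,
    aggregate_channels,
    attention,
    bce_loss,
    classify,
    embed_patches,
    instance_normalize,
    make_patches,
    patch_count,
    pool_tokens,
)

TINY = dict(n_layers=1, n_heads=2, d_model=8, d_ff=8, seq_len=16,
            patch_len=4, stride=4, dropout=0.0, fc_dropout=0.0, attn_dropout=0.0)


# ------------------------------------------------------ instance normalisation
def test_instance_norm_hand_example():
    out, stats = instance_normalize([1.0, 2.0, 3.0, 4.0])
    assert stats.mu == pytest.approx(2.5)
    assert stats.sigma == pytest.approx(np.sqrt(1.25))
    assert out == pytest.approx([-1.3416, -0.4472, 0.4472, 1.3416], abs=1e-4)


def test_instance_norm_constant_signal_maps_to_zero():
    out, _ = instance_normalize(np.full(10, 7.0))
    assert np.all(out == 0.0)


def test_instance_norm_idempotent_on_standardised_input():
    x = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)  # mean 0, population SD 1
    out, _ = instance_normalize(x)
    assert out == pytest.approx(x, abs=1e-6)


def test_instance_norm_uses_observed_positions_only():
    values = np.array([1.0, 2.0, 3.0, 4.0, 99.0])
    mask = np.array([True, True, True, True, False])
    out, stats = instance_normalize(values, mask)
    assert stats.mu == pytest.approx(2.5)
    assert out[4] == 0.0  # masked position zero-filled


def test_instance_norm_all_missing_channel_raises():
    with pytest.raises(DegenerateChannelError):
        instance_normalize([1.0, 2.0], [False, False])


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_instance_norm_contract_under_fuzzed_masks(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(8, 200)
    x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3.0), size=n)
    mask = rng.random(n) > 0.3
    if mask.sum() < 2:
        mask[:2] = True
    out, _ = instance_normalize(x, mask)
    obs = out[mask]
    assert abs(obs.mean()) < 1e-6
    assert abs(obs.std() - 1.0) < 1e-4


# ------------------------------------------------------------------- patching
@pytest.mark.parametrize(
    "L,P,S,expected_n", [(960, 16, 16, 60), (10, 10, 10, 1), (10, 4, 2, 4)]
)
def test_patch_count_examples(L, P, S, expected_n):
    assert patch_count(L, P, S) == expected_n


def test_make_patches_enumerates_strided_segments():
    series = np.arange(10.0)
    ps = make_patches(series, np.ones(10, bool), patch_len=4, stride=2)
    assert ps.n == 4
    starts = [0, 2, 4, 6]
    for j, s in enumerate(starts):
        assert np.array_equal(ps.patches[j], series[s : s + 4])


def test_patch_validity_threshold_half_observed():
    mask = np.ones(8, bool)
    mask[:3] = False  # first patch of 4 has 1/4 observed, second has 4/4
    ps = make_patches(np.arange(8.0), mask, 4, 4)
    assert list(ps.patch_valid) == [False, True]


def test_patch_len_exceeding_series_raises():
    with pytest.raises(ParameterError):
        patch_count(8, 9, 4)


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_patch_count_law_matches_enumeration(data):
    """N = floor((L-P)/S) + 1 against explicit enumeration of start offsets."""
    L = data.draw(st.integers(1, 300))
    P = data.draw(st.integers(1, L))
    S = data.draw(st.integers(1, 40))
    starts = [s for s in range(0, L, S) if s + P <= L]
    # enumeration counts every stride-multiple start with a full patch inside
    assert patch_count(L, P, S) == len(starts)
    ps = make_patches(np.arange(float(L)), np.ones(L, bool), P, S)
    assert ps.n == len(starts)


# ------------------------------------------------------------------ embedding
def test_embed_zero_weights_gives_zero_tokens():
    ps = make_patches(np.arange(8.0), np.ones(8, bool), 4, 4)
    tokens = embed_patches(ps, np.zeros((4, 3)), np.zeros((2, 3)))
    assert np.all(tokens == 0.0)


def test_embed_identical_patches_differ_only_by_positional_rows():
    patches = np.tile(np.arange(4.0), (3, 1))
    ps = make_patches(np.tile(np.arange(4.0), 3), np.ones(12, bool), 4, 4)
    assert np.array_equal(ps.patches, patches)
    W_pos = np.arange(6.0).reshape(3, 2)
    tokens = embed_patches(ps, np.ones((4, 2)), W_pos)
    diffs = tokens - tokens[0]
    assert np.allclose(diffs, W_pos - W_pos[0])


def test_embed_hand_matrix_product():
    ps = make_patches(np.array([1.0, 2.0]), np.ones(2, bool), 2, 2)
    W_P = np.array([[1.0, 0.0], [0.0, 2.0]])
    W_pos = np.array([[0.5, -0.5]])
    assert np.allclose(embed_patches(ps, W_P, W_pos), [[1.5, 3.5]])


# ------------------------------------------------------------------ attention
def test_attention_single_valid_token_returns_its_value():
    Q = K = np.array([[1.0, 2.0]])
    V = np.array([[3.0, 4.0]])
    assert attention(Q, K, V) == pytest.approx(V)


def test_attention_identical_keys_average_values():
    K = np.ones((3, 2))
    Q = np.random.default_rng(0).normal(size=(3, 2))
    V = np.array([[1.0], [2.0], [3.0]])
    assert attention(Q, K, V) == pytest.approx(np.full((3, 1), 2.0))


def test_attention_scalar_softmax_hand_example():
    Q = np.array([[1.0], [0.0]])
    K = np.array([[1.0], [0.0]])
    V = np.array([[1.0], [0.0]])
    out = attention(Q, K, V)
    w = np.exp(1.0) / (np.exp(1.0) + 1.0)  # softmax(1, 0) = (0.731, 0.269)
    assert out[0, 0] == pytest.approx(w, abs=1e-3)
    assert out[0, 0] == pytest.approx(0.731, abs=1e-3)


def test_attention_invalid_keys_get_zero_weight_and_queries_zero_context():
    rng = np.random.default_rng(0)
    K = rng.normal(size=(3, 2))
    V = rng.normal(size=(3, 2))
    valid = np.array([True, True, False])
    out = attention(K, K, V, valid)
    # invalid token's value row must not influence valid outputs
    V2 = V.copy()
    V2[2] = 99.0
    assert np.array_equal(out[:2], attention(K, K, V2, valid)[:2])
    assert np.all(out[2] == 0.0)


def test_attention_all_keys_invalid_raises():
    with pytest.raises(CTGError):
        attention(np.ones((1, 2)), np.ones((1, 2)), np.ones((1, 2)), [False])


# ----------------------------------------------------------- pooling and head
def test_pool_mean_and_masked_exclusion():
    tokens = np.array([[0.0, 2.0], [2.0, 0.0]])
    assert pool_tokens(tokens) == pytest.approx([1.0, 1.0])
    tokens = np.array([[5.0, 5.0], [9.0, 9.0]])
    assert pool_tokens(tokens, [True, False]) == pytest.approx([5.0, 5.0])
    with pytest.raises(DegenerateWindowError):
        pool_tokens(tokens, [False, False])


def test_aggregate_concatenation_order_is_fhr_first():
    out = aggregate_channels([1.0, 2.0], [3.0, 4.0])
    assert np.array_equal(out, [1.0, 2.0, 3.0, 4.0])
    assert not np.array_equal(out, aggregate_channels([3.0, 4.0], [1.0, 2.0]))


def test_classify_sigmoid_examples():
    assert classify([0.0], [0.0], 0.0).probability == pytest.approx(0.5)
    assert classify([1.0], [2.0], -1.0).probability == pytest.approx(0.7311, abs=1e-4)
    assert classify([100.0], [10.0], 0.0).probability == pytest.approx(1.0)
    assert classify([0.6], [1.0], 0.0).label == 1  # >= 0.5 decision rule


def test_bce_examples_and_symmetry():
    assert bce_loss(1, 1 - 1e-9) == pytest.approx(0.0, abs=1e-6)
    assert bce_loss(1, 0.5) == pytest.approx(np.log(2.0))
    for p in (0.1, 0.4, 0.9):
        assert bce_loss(0, p) == pytest.approx(bce_loss(1, 1 - p))
    with pytest.raises(ParameterError):
        bce_loss(0.3, 0.5)


# ------------------------------------------------------------- encoder layer
def test_encoder_zero_weights_is_double_layernorm_passthrough():
    cfg = ModelConfig(**TINY)
    layer = EncoderLayer(cfg, np.random.default_rng(0))
    for p in (layer.Wq, layer.bq, layer.Wk, layer.bk, layer.Wv, layer.bv,
              layer.Wo, layer.bo, layer.W1, layer.b1, layer.W2, layer.b2):
        p.data[...] = 0.0
    x = np.random.default_rng(1).normal(size=(1, 4, 8))
    out = layer(Tensor(x), np.zeros((1, 1, 1, 4))).data

    def ln(a):
        mu = a.mean(-1, keepdims=True)
        sd = np.sqrt(((a - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
        return (a - mu) / sd

    assert np.allclose(out, ln(ln(x)), atol=1e-10)


# ---------------------------------------------------------------- forward pass
def _rand_window(rng, cfg, missing=0.2):
    v = rng.random((1, cfg.n_channels, cfg.seq_len))
    m = rng.random((1, cfg.n_channels, cfg.seq_len)) > missing
    m[:, :, :2] = True  # keep every channel alive
    return v, m


def test_forward_eval_mode_is_deterministic():
    cfg = ModelConfig(**TINY)
    net = PatchTransformerNet(cfg, seed=0)
    v, m = _rand_window(np.random.default_rng(0), cfg)
    assert np.array_equal(net.predict_proba(v, m), net.predict_proba(v, m))


def test_forward_ignores_values_at_masked_positions():
    cfg = ModelConfig(**TINY)
    net = PatchTransformerNet(cfg, seed=0)
    rng = np.random.default_rng(2)
    v, m = _rand_window(rng, cfg)
    p_ref = net.predict_proba(v, m)
    v2 = v.copy()
    v2[~m] = rng.normal(size=(~m).sum()) * 50
    assert np.array_equal(p_ref, net.predict_proba(v2, m))


def test_channel_paths_are_independent_up_to_aggregation():
    cfg = ModelConfig(**TINY)
    net = PatchTransformerNet(cfg, seed=0)
    rng = np.random.default_rng(3)
    v, m = _rand_window(rng, cfg, missing=0.0)

    def pooled_fhr(values):
        x, pv = net._prepare(values, m)
        path = net.channels[0]
        tok = Tensor(x[:, 0][..., net._idx]) @ path.W_P + path.W_pos
        bias = np.where(pv[:, 0], 0.0, -1e9)[:, None, None, :]
        for layer in path.layers:
            tok = layer(tok, bias)
        return tok.data

    ref = pooled_fhr(v)
    v_toco = v.copy()
    v_toco[:, 1] = rng.random(cfg.seq_len)  # perturb TOCO only
    assert np.array_equal(ref, pooled_fhr(v_toco))
    assert not np.array_equal(net.predict_proba(v, m),
                              net.predict_proba(v_toco, m))


def test_attention_rows_sum_to_one_over_valid_keys():
    cfg = ModelConfig(**TINY)
    layer = EncoderLayer(cfg, np.random.default_rng(0))
    x = Tensor(np.random.default_rng(1).normal(size=(1, 4, 8)))
    valid = np.array([[True, True, False, True]])
    bias = np.where(valid, 0.0, -1e9)[:, None, None, :]
    h, dk = cfg.n_heads, cfg.d_head
    q = (x @ layer.Wq + layer.bq).reshape(1, 4, h, dk).transpose((0, 2, 1, 3))
    k = (x @ layer.Wk + layer.bk).reshape(1, 4, h, dk).transpose((0, 2, 1, 3))
    w = (((q @ k.swapaxes(-1, -2)) * (1 / np.sqrt(dk))) + bias).softmax(-1).data
    assert np.allclose(w.sum(-1), 1.0)
    assert np.all(w[..., ~valid[0]] < 1e-12)  # invalid keys carry no weight


def test_forward_matches_straight_line_composition():
    """Network forward vs an independent hand-composed numpy forward pass."""
    cfg = ModelConfig(n_layers=1, n_heads=1, d_model=4, d_ff=4, seq_len=8,
                      patch_len=4, stride=4, dropout=0.0, fc_dropout=0.0,
                      attn_dropout=0.0)
    net = PatchTransformerNet(cfg, seed=5)
    rng = np.random.default_rng(7)
    v = rng.random((1, 2, 8))
    m = np.ones((1, 2, 8), bool)
    got = net.predict_proba(v, m)[0]

    def ln(a, g, b):
        mu = a.mean(-1, keepdims=True)
        sd = np.sqrt(((a - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
        return (a - mu) / sd * g + b

    pooled = []
    for c, path in enumerate(net.channels):
        x = v[0, c]
        x = (x - x.mean()) / (x.std() + 1e-8)
        patches = x.reshape(2, 4)
        tok = patches @ path.W_P.data + path.W_pos.data
        lay = path.layers[0]
        q = tok @ lay.Wq.data + lay.bq.data
        k = tok @ lay.Wk.data + lay.bk.data
        val = tok @ lay.Wv.data + lay.bv.data
        s = q @ k.T / 2.0  # sqrt(d_k) = 2
        w = np.exp(s - s.max(-1, keepdims=True))
        w = w / w.sum(-1, keepdims=True)
        mhsa = (w @ val) @ lay.Wo.data + lay.bo.data
        tok = ln(tok + mhsa, lay.ln1_g.data, lay.ln1_b.data)
        ffn = np.maximum(tok @ lay.W1.data + lay.b1.data, 0) @ lay.W2.data + lay.b2.data
        tok = ln(tok + ffn, lay.ln2_g.data, lay.ln2_b.data)
        pooled.append(tok.mean(axis=0))
    g = np.concatenate(pooled)
    logit = g @ net.W_c.data.ravel() + net.b_c.data[0]
    expected = 1.0 / (1.0 + np.exp(-logit))
    assert got == pytest.approx(expected, abs=1e-10)


def test_smoothing_kernel_identity_at_init():
    """The optional input smoother starts as an exact identity map."""
    cfg = ModelConfig(**{**TINY, "smooth_kernel": 5})
    net = PatchTransformerNet(cfg, seed=0)
    x = np.random.default_rng(0).normal(size=(2, cfg.seq_len))
    out = net._smooth_channel(x, net.channels[0].conv).data
    assert np.allclose(out, x)
    v = np.random.default_rng(1).random((2, 2, cfg.seq_len))
    m = np.ones_like(v, dtype=bool)
    assert np.all(np.isfinite(net.predict_proba(v, m)))


def test_config_invariants_enforced():
    with pytest.raises(ParameterError):
        ModelConfig(d_model=10, n_heads=4)
    with pytest.raises(ParameterError):
        ModelConfig(patch_len=32, seq_len=16)
    with pytest.raises(ParameterError):
        ModelConfig(dropout=1.0)
    with pytest.raises(ParameterError):
        ModelConfig(activation="swish")
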