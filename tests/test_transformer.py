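"""Attention correctness against a brute-force oracle; stack behaviour;
exact parameter accounting."""

import numpy as np
import pytest

from sonoseg.autodiff import Tensor
from sonoseg.transformer import (ModelConfig, attention, count_parameters,
                                 cross_attention_block, decoder_forward,
                                 encoder_forward, init_mae_params,
                                 init_seg_params, layer_norm, load_checkpoint,
                                 save_checkpoint, self_attention_block,
                                 _mha_cross, _mha_self)


def brute_force_attention(Q, K, V):
    """Independent double-loop softmax attention."""
    out = np.zeros((Q.shape[0], V.shape[1]))
    for i in range(Q.shape[0]):
        logits = np.array([Q[i] @ K[j] / np.sqrt(Q.shape[1])
                           for j in range(K.shape[0])])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        for j in range(K.shape[0]):
            out[i] += w[j] * V[j]
    return out


def test_attention_matches_brute_force_oracle():
    rng = np.random.default_rng(99)
    for _ in range(100):
        lq = int(rng.integers(1, 9))
        lkv = int(rng.integers(1, 9))
        dk = int(rng.integers(1, 9))
        dv = int(rng.integers(1, 9))
        Q = rng.normal(size=(lq, dk))
        K = rng.normal(size=(lkv, dk))
        V = rng.normal(size=(lkv, dv))
        np.testing.assert_allclose(attention(Q, K, V).data,
                                   brute_force_attention(Q, K, V), atol=1e-6)


def test_attention_singleton_kv_returns_value_row(rng):
    Q = rng.normal(size=(5, 4))
    K = rng.normal(size=(1, 4))
    V = rng.normal(size=(1, 3))
    out = attention(Q, K, V).data
    np.testing.assert_allclose(out, np.tile(V, (5, 1)), atol=1e-12)


def test_attention_identical_keys_average_values(rng):
    Q = rng.normal(size=(4, 6))
    K = np.tile(rng.normal(size=(1, 6)), (7, 1))
    V = rng.normal(size=(7, 2))
    np.testing.assert_allclose(attention(Q, K, V).data,
                               np.tile(V.mean(axis=0), (4, 1)), atol=1e-12)


def test_attention_dk_mismatch_raises(rng):
    with pytest.raises(ValueError, match="d_k"):
        attention(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)),
                  rng.normal(size=(3, 5)))


def _tiny():
    return ModelConfig(patch_size=2, image_size=8, embed_dim=12,
                       encoder_layers=2, mae_decoder_layers=2,
                       seg_decoder_layers=1, heads=2, channels=1)


def test_block_with_zero_output_projections_is_identity(rng):
    cfg = _tiny()
    params = init_seg_params(cfg, np.random.default_rng(0))
    params["encoder.0.attn.proj.weight"].data[:] = 0.0
    params["encoder.0.ff.fc2.weight"].data[:] = 0.0
    x = rng.normal(size=(cfg.num_patches, cfg.embed_dim))
    out = self_attention_block(x, params, "encoder.0", cfg)
    np.testing.assert_allclose(out.data, x, atol=1e-12)


def test_block_permutation_equivariance(rng):
    cfg = _tiny()
    params = init_seg_params(cfg, np.random.default_rng(1))
    x = rng.normal(size=(cfg.num_patches, cfg.embed_dim))
    perm = rng.permutation(cfg.num_patches)
    out = self_attention_block(x, params, "encoder.1", cfg).data
    out_perm = self_attention_block(x[perm], params, "encoder.1", cfg).data
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)
    assert out.shape == (cfg.num_patches, cfg.embed_dim)


def test_cross_attention_with_tied_projections_equals_self(rng):
    cfg = _tiny()
    params = init_seg_params(
        ModelConfig(**{**cfg.__dict__, "use_cross_attention": True}),
        np.random.default_rng(2))
    D = cfg.embed_dim
    x = Tensor(rng.normal(size=(cfg.num_patches, D)))
    # tie: cross projections = the self-attention QKV split, biases zeroed
    qkv = params["decoder.0.attn.qkv.weight"].data
    params["decoder.0.attn.qkv.bias"].data[:] = 0.0
    params["decoder.0.attn.proj.bias"].data[:] = 0.0
    params["decoder.0.cross0.q.weight"].data = qkv[:, :D].copy()
    params["decoder.0.cross0.k.weight"].data = qkv[:, D:2 * D].copy()
    params["decoder.0.cross0.v.weight"].data = qkv[:, 2 * D:].copy()
    params["decoder.0.cross0.proj.weight"].data = \
        params["decoder.0.attn.proj.weight"].data.copy()
    self_out = _mha_self(x, params, "decoder.0.attn", cfg.heads)
    cross_out = _mha_cross(x, x, params, "decoder.0.cross0", cfg.heads)
    np.testing.assert_allclose(cross_out.data, self_out.data, atol=1e-10)


def test_cross_block_zero_projection_reduces_to_plain_block(rng):
    cfg = ModelConfig(**{**_tiny().__dict__, "use_cross_attention": True})
    params = init_seg_params(cfg, np.random.default_rng(3))
    for j in range(cfg.cross_per_layer):
        params[f"decoder.0.cross{j}.proj.weight"].data[:] = 0.0
    x = rng.normal(size=(cfg.num_patches, cfg.embed_dim))
    mem = rng.normal(size=(cfg.num_patches, cfg.embed_dim))
    out = cross_attention_block(x, mem, params, "decoder.0", cfg)
    plain = self_attention_block(x, params, "decoder.0", cfg)
    np.testing.assert_allclose(out.data, plain.data, atol=1e-12)


def test_cross_attention_single_memory_token_broadcasts(rng):
    cfg = ModelConfig(**{**_tiny().__dict__, "use_cross_attention": True})
    params = init_seg_params(cfg, np.random.default_rng(4))
    x = Tensor(rng.normal(size=(5, cfg.embed_dim)))
    mem = Tensor(rng.normal(size=(1, cfg.embed_dim)))
    out = _mha_cross(x, mem, params, "decoder.0.cross0", cfg.heads).data
    expected = (mem.data @ params["decoder.0.cross0.v.weight"].data
                @ params["decoder.0.cross0.proj.weight"].data)
    np.testing.assert_allclose(out, np.tile(expected, (5, 1)), atol=1e-10)


def test_encoder_returns_all_layer_outputs(rng):
    cfg = _tiny()
    params = init_seg_params(cfg, np.random.default_rng(5))
    x = rng.normal(size=(cfg.num_patches, cfg.embed_dim))
    final, per_layer = encoder_forward(x, cfg, params)
    assert len(per_layer) == cfg.encoder_layers
    for out in per_layer:
        assert out.shape == (cfg.num_patches, cfg.embed_dim)
    g = params["encoder_norm.gamma"]
    b = params["encoder_norm.beta"]
    np.testing.assert_allclose(final.data,
                               layer_norm(per_layer[-1], g, b).data)
    # deterministic
    final2, _ = encoder_forward(x, cfg, params)
    np.testing.assert_array_equal(final.data, final2.data)


def test_decoder_without_variant_ignores_encoder_outputs(rng):
    cfg = _tiny()
    params = init_seg_params(cfg, np.random.default_rng(6))
    x = rng.normal(size=(cfg.num_patches, cfg.embed_dim))
    junk = [Tensor(rng.normal(size=x.shape)) for _ in range(cfg.encoder_layers)]
    a = decoder_forward(x, None, cfg, params).data
    b = decoder_forward(x, junk, cfg, params).data
    np.testing.assert_array_equal(a, b)
    assert a.shape == (cfg.num_patches, cfg.embed_dim)


def test_decoder_variant_with_zero_memories_matches_plain(rng):
    base = _tiny()
    cross_cfg = ModelConfig(**{**base.__dict__, "use_cross_attention": True})
    params = init_seg_params(cross_cfg, np.random.default_rng(7))
    x = rng.normal(size=(base.num_patches, base.embed_dim))
    zeros = [Tensor(np.zeros((base.num_patches, base.embed_dim)))
             for _ in range(base.encoder_layers)]
    with_zero_mem = decoder_forward(x, zeros, cross_cfg, params).data
    plain = decoder_forward(x, None, cross_cfg, params, use_cross=False).data
    np.testing.assert_allclose(with_zero_mem, plain, atol=1e-12)
    with pytest.raises(ValueError):
        decoder_forward(x, None, cross_cfg, params)


def test_parameter_count_matches_hand_formula():
    cfg = _tiny()
    D, h = cfg.embed_dim, cfg.ff_hidden
    block = 4 * D + 3 * D * D + 3 * D + D * D + D + 2 * D * h + h + D
    embed = cfg.patch_dim_c * D + D
    pos = cfg.num_patches * D
    head = D * cfg.head_out_dim + cfg.head_out_dim
    n_blocks = cfg.encoder_layers + cfg.seg_decoder_layers
    expected = embed + pos + n_blocks * block + 4 * D + head
    assert count_parameters(cfg) == expected
    cross = ModelConfig(**{**cfg.__dict__, "use_cross_attention": True})
    per_cross = 2 * D + 4 * D * D
    assert count_parameters(cross) == expected + \
        cfg.seg_decoder_layers * cfg.cross_per_layer * per_cross


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        ModelConfig(embed_dim=50, heads=3)
    with pytest.raises(ValueError):
        ModelConfig(patch_size=9, image_size=224)
    assert ModelConfig().head_out_dim == 196
    assert ModelConfig().cross_taps == ((12, 10), (8, 6), (4, 2))


def test_checkpoint_roundtrip_bitwise(tmp_path):
    cfg = _tiny()
    params = init_mae_params(cfg, np.random.default_rng(8))
    path = tmp_path / "model.ckpt"
    save_checkpoint(path, params, cfg, meta={"stage": "mae"})
    loaded, loaded_cfg, meta = load_checkpoint(path)
    assert loaded_cfg == cfg
    assert meta["stage"] == "mae"
    assert set(loaded) == set(params)
    for k in params:
        np.testing.assert_array_equal(loaded[k].data, params[k].data)
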