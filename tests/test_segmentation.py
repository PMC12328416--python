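"""Dice identities, forward contracts, weight transfer, fine-tuning loop."""

import numpy as np
import pytest

from sonoseg.segmentation import (TransferError, dice_loss, dice_score,
                                  evaluate, finetune, seg_forward,
                                  transfer_weights)
from sonoseg.training import TrainConfig
from sonoseg.transformer import ModelConfig, init_mae_params, init_seg_params


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def test_soft_dice_identities():
    truth = np.zeros((40, 40))
    truth[:10, :10] = 1.0
    assert float(dice_loss(truth.copy(), truth).data) == pytest.approx(0.0)
    disjoint = np.zeros_like(truth)
    disjoint[20:30, 20:30] = 1.0
    assert float(dice_loss(disjoint, truth).data) > 0.99
    half = np.zeros_like(truth)
    half[:10, 5:15] = 1.0  # 100 px predicted, 50 overlap
    assert float(dice_loss(half, truth).data) == pytest.approx(0.5, abs=0.01)


def test_soft_dice_monotone_in_overlap():
    truth = np.zeros(100)
    truth[:50] = 1.0
    losses = []
    for overlap in (10, 25, 40, 50):
        pred = np.zeros(100)
        pred[50 - overlap:100 - overlap] = 1.0  # always 50 px predicted
        losses.append(float(dice_loss(pred, truth).data))
    assert losses == sorted(losses, reverse=True)


def test_hard_dice_conventions():
    empty = np.zeros((8, 8), dtype=bool)
    assert dice_score(empty, empty).dice == pytest.approx(1.0)
    full = np.ones((8, 8), dtype=bool)
    assert dice_score(full, full).dice == pytest.approx(1.0)
    truth = np.zeros((10, 10), dtype=bool)
    truth[:6, :5] = True  # 30 px
    pred = np.zeros_like(truth)
    pred[:2, :5] = True  # 10 px subset
    res = dice_score(pred, truth)
    assert res.dice == pytest.approx(2 * 10 / 40, abs=1e-6)
    assert (res.intersection, res.size_pred, res.size_truth) == (10, 10, 30)


def test_dice_shape_mismatch_errors():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((4, 4)), np.zeros((5, 5)))
    with pytest.raises(ValueError):
        dice_score(np.zeros((4, 4)), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def test_seg_forward_contract(tiny_cfg, rng):
    params = init_seg_params(tiny_cfg)
    pred = seg_forward(rng.random((80, 70)), tiny_cfg, params)
    L, p2 = tiny_cfg.num_patches, tiny_cfg.head_out_dim
    assert pred.per_patch_probs.shape == (L, p2)
    assert pred.assembled_mask_prob.shape == (56, 56)
    assert np.all(pred.assembled_mask_prob > 0) and np.all(pred.assembled_mask_prob < 1)
    assert pred.binary_mask.dtype == bool
    np.testing.assert_array_equal(pred.binary_mask,
                                  pred.assembled_mask_prob >= 0.5)


# ---------------------------------------------------------------------------
# transfer
# ---------------------------------------------------------------------------

def test_transfer_copies_encoder_bitwise_and_drops_last_decoder_layer(tiny_cfg):
    mae_params = init_mae_params(tiny_cfg, np.random.default_rng(0))
    seg_params, report = transfer_weights(mae_params, tiny_cfg, tiny_cfg)
    for name, tensor in seg_params.items():
        if name in report["transferred"]:
            np.testing.assert_array_equal(tensor.data, mae_params[name].data)
    # dropped: exactly the deepest MAE decoder layer + mask token + recon head
    dropped_layers = {n.split(".")[1] for n in report["dropped"]
                      if n.startswith("decoder.")}
    assert dropped_layers == {str(tiny_cfg.mae_decoder_layers - 1)}
    assert "mask_token" in report["dropped"]
    assert any(n.startswith("recon_head") for n in report["dropped"])
    # decoder layers below the dropped one transferred
    assert any(n.startswith("decoder.0.") for n in report["transferred"])
    # segmentation head freshly initialised
    assert "head.weight" in report["fresh"] and "head.bias" in report["fresh"]


def test_transfer_into_cross_variant_leaves_cross_layers_fresh(tiny_cfg):
    mae_params = init_mae_params(tiny_cfg, np.random.default_rng(1))
    cross_cfg = ModelConfig(**{**tiny_cfg.__dict__, "use_cross_attention": True})
    seg_params, report = transfer_weights(mae_params, tiny_cfg, cross_cfg)
    cross_names = [n for n in seg_params if ".cross" in n]
    assert cross_names
    assert all(n in report["fresh"] for n in cross_names)


def test_transfer_rejects_width_mismatch(tiny_cfg):
    mae_params = init_mae_params(tiny_cfg, np.random.default_rng(2))
    wrong = ModelConfig(**{**tiny_cfg.__dict__, "embed_dim": 96})
    with pytest.raises(TransferError, match="embed_dim"):
        transfer_weights(mae_params, tiny_cfg, wrong)


def test_transfer_rejects_too_shallow_pretrained_decoder(tiny_cfg):
    mae_params = init_mae_params(tiny_cfg, np.random.default_rng(3))
    deeper = ModelConfig(**{**tiny_cfg.__dict__, "seg_decoder_layers": 3})
    with pytest.raises(TransferError, match="fewer layers"):
        transfer_weights(mae_params, tiny_cfg, deeper)


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def test_finetune_zero_lr_constant_history(small_corpus, tiny_cfg):
    tc = TrainConfig(epochs=3, batch_size=4, lr=0.0, weight_decay=0.0,
                     augment=False, seed=0)
    _, history = finetune(small_corpus["pairs"][:4], None, tiny_cfg, tc)
    assert max(history) - min(history) < 1e-12


def test_finetune_does_not_mutate_init_params(small_corpus, tiny_cfg):
    mae_params = init_mae_params(tiny_cfg, np.random.default_rng(4))
    init, _ = transfer_weights(mae_params, tiny_cfg, tiny_cfg)
    before = {k: v.data.copy() for k, v in init.items()}
    tc = TrainConfig(epochs=2, batch_size=4, lr=1e-3, augment=False, seed=1)
    finetune(small_corpus["pairs"][:4], init, tiny_cfg, tc)
    for k in init:
        np.testing.assert_array_equal(init[k].data, before[k])


def test_early_stopping_halts_on_stagnation(small_corpus, tiny_cfg):
    tc = TrainConfig(epochs=50, batch_size=4, lr=0.0, augment=False,
                     early_stop_patience=5, seed=0)
    _, history = finetune(small_corpus["pairs"][:4], None, tiny_cfg, tc)
    assert len(history) == 6  # first epoch improves on +inf, then 5 stale


def test_evaluate_table_and_mean(small_corpus, tiny_cfg):
    params = init_seg_params(tiny_cfg)
    mean_dice, table = evaluate(small_corpus["pairs"], tiny_cfg, params)
    assert len(table) == len(small_corpus["pairs"])
    assert mean_dice == pytest.approx(np.mean([r["dice"] for r in table]),
                                      abs=1e-12)
    assert all(0.0 <= r["dice"] <= 1.0 for r in table)
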