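"""Segmentation fine-tuning: ViT encoder-decoder, Dice loss, weight transfer.

The segmentation network reuses the pre-training architecture but feeds
every patch token through the 12-layer encoder and a 3-layer decoder; a
per-token linear head emits one logit per patch pixel, a sigmoid turns
them into probabilities and the patches reassemble into a full-resolution
soft mask.  Because the pre-trained decoder has four layers and the
segmentation decoder three, the last pre-trained decoder layer is dropped
when the weights are carried over; the reconstruction head and the mask
token have no counterpart and are discarded, while the segmentation head
(and the cross-attention sublayers, if enabled — they were never
pre-trained) start from fresh initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, sigmoid
from .patches import patchify, resize_normalize, tile_channels, unpatchify
from .training import AdamW, TrainConfig, augment_pair, check_finite, substream
from .transformer import (ModelConfig, decoder_forward, encoder_forward,
                          init_seg_params)

__all__ = ["SegPrediction", "DiceResult", "seg_forward", "dice_loss",
           "dice_score", "transfer_weights", "finetune", "evaluate",
           "TransferError"]

SOFT_DICE_EPS = 1.0
HARD_DICE_EPS = 1e-6
BINARY_THRESHOLD = 0.5


@dataclass(frozen=True)
class SegPrediction:
    """Per-patch probabilities and their assembled image-space form."""

    per_patch_probs: np.ndarray      # (L, p*p), in (0, 1)
    assembled_mask_prob: np.ndarray  # (image_size, image_size)
    binary_mask: np.ndarray          # thresholded at 0.5


@dataclass(frozen=True)
class DiceResult:
    dice: float
    intersection: float
    size_pred: float
    size_truth: float
    eps: float


class TransferError(ValueError):
    """Raised when a pre-trained checkpoint cannot be mapped onto a model."""


def seg_probs_tensor(image: np.ndarray, cfg: ModelConfig, params: dict) -> Tensor:
    """Differentiable forward pass to per-patch probabilities (L, p*p)."""
    grid = cfg.grid
    image = resize_normalize(image, cfg.image_size)
    raw = tile_channels(patchify(image, grid), cfg.channels)
    tokens = Tensor(raw) @ params["patch_embed.weight"] + params["patch_embed.bias"]
    tokens = tokens + params["pos_embed"]
    enc_final, per_layer = encoder_forward(tokens, cfg, params)
    dec = decoder_forward(enc_final, per_layer, cfg, params)
    logits = dec @ params["head.weight"] + params["head.bias"]
    return sigmoid(logits)


def seg_forward(image: np.ndarray, cfg: ModelConfig, params: dict) -> SegPrediction:
    """Predict a nodule mask for one image (no masking, all tokens used)."""
    probs = seg_probs_tensor(image, cfg, params).data
    assembled = unpatchify(probs, cfg.grid)
    return SegPrediction(per_patch_probs=probs,
                         assembled_mask_prob=assembled,
                         binary_mask=assembled >= BINARY_THRESHOLD)


def dice_loss(pred_probs, truth_mask, eps: float = SOFT_DICE_EPS):
    """Soft Dice loss ``1 - (2 sum(p*g) + eps) / (sum p + sum g + eps)``.

    Accepts a Tensor (differentiable path) or array of probabilities in
    any shape matching the binary truth after flattening.
    """
    p = pred_probs if isinstance(pred_probs, Tensor) else Tensor(pred_probs)
    g = np.asarray(truth_mask, dtype=np.float64)
    if p.size != g.size:
        raise ValueError(f"prediction has {p.size} elements, truth {g.size}")
    p = p.reshape(p.size)
    g = g.reshape(g.size)
    inter = (p * g).sum()
    dice = (2.0 * inter + eps) / (p.sum() + float(g.sum()) + eps)
    return 1.0 - dice


def dice_score(binary_pred, truth_mask, eps: float = HARD_DICE_EPS) -> DiceResult:
    """Hard Dice overlap between two binary masks (empty vs empty -> 1)."""
    p = np.asarray(binary_pred).astype(bool)
    g = np.asarray(truth_mask).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    inter = float(np.logical_and(p, g).sum())
    sp, sg = float(p.sum()), float(g.sum())
    return DiceResult(dice=(2.0 * inter + eps) / (sp + sg + eps),
                      intersection=inter, size_pred=sp, size_truth=sg, eps=eps)


# ---------------------------------------------------------------------------
# weight transfer
# ---------------------------------------------------------------------------

def transfer_weights(mae_params: dict, mae_cfg: ModelConfig,
                     seg_cfg: ModelConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[dict, dict]:
    """Map pre-trained MAE weights onto a segmentation model.

    Copies the patch embedding, positional table, all encoder layers (plus
    final encoder norm) and the first ``seg_decoder_layers`` decoder
    layers verbatim; drops the remaining MAE decoder layer(s), the
    reconstruction head and the mask token; initialises the segmentation
    head and any cross-attention sublayers fresh.  Returns
    ``(params, report)`` where the report lists transferred / dropped /
    freshly initialised entries.  Raises :class:`TransferError` listing
    every incompatible entry if the architectures disagree.
    """
    for attr in ("embed_dim", "patch_size", "image_size", "encoder_layers",
                 "channels", "heads", "ff_ratio"):
        a, b = getattr(mae_cfg, attr), getattr(seg_cfg, attr)
        if a != b:
            raise TransferError(f"checkpoint/config mismatch on {attr}: {a} vs {b}")
    if mae_cfg.mae_decoder_layers < seg_cfg.seg_decoder_layers:
        raise TransferError("pre-trained decoder has fewer layers than the "
                            "segmentation decoder")
    params = init_seg_params(seg_cfg, rng or np.random.default_rng(seg_cfg.init_seed))
    transferred, mismatched = [], []
    for name, target in params.items():
        if name not in mae_params:
            continue
        source = mae_params[name]
        src = source.data if isinstance(source, Tensor) else np.asarray(source)
        if src.shape != target.data.shape:
            mismatched.append(f"{name}: checkpoint {src.shape} vs model "
                              f"{target.data.shape}")
            continue
        target.data = src.copy()
        transferred.append(name)
    if mismatched:
        raise TransferError("incompatible checkpoint entries:\n  " +
                            "\n  ".join(mismatched))
    dropped = sorted(set(mae_params) - set(transferred))
    fresh = sorted(set(params) - set(transferred))
    return params, {"transferred": sorted(transferred), "dropped": dropped,
                    "fresh": fresh}


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def finetune(dataset, init: dict | None, cfg: ModelConfig,
             train_cfg: TrainConfig) -> tuple[dict, list[float]]:
    """Dice-loss fine-tuning with AdamW; returns (params, loss history).

    ``dataset`` is a sequence of (image, binary mask) pairs.  ``init`` is
    either a parameter dict (e.g. from :func:`transfer_weights`; it is
    deep-copied, the argument is left untouched) or ``None`` for training
    from scratch.  Early stopping engages when ``early_stop_patience`` is
    positive: training stops once the epoch loss has failed to improve by
    ``early_stop_min_delta`` for that many consecutive epochs.
    """
    pairs = list(dataset)
    if not pairs:
        raise ValueError("dataset is empty")
    if init is None:
        params = init_seg_params(cfg, substream(train_cfg.seed, "seg", "init"))
    else:
        params = {k: Tensor(v.data.copy() if isinstance(v, Tensor) else np.array(v),
                            requires_grad=True, name=k) for k, v in init.items()}
    opt = AdamW(params, train_cfg)
    grid = cfg.grid
    history: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(train_cfg.epochs):
        # reset streams each epoch: randomness is a fixed function of the seed
        rng_order = substream(train_cfg.seed, "seg", "order")
        rng_aug = substream(train_cfg.seed, "seg", "augment")
        order = rng_order.permutation(len(pairs))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            opt.zero_grad()
            batch_loss = None
            for idx in batch:
                img, mask = pairs[idx]
                img = resize_normalize(img, cfg.image_size)
                mask = _resize_mask(mask, cfg.image_size)
                if train_cfg.augment:
                    img, mask = augment_pair(img, mask, train_cfg, rng_aug)
                probs = seg_probs_tensor(img, cfg, params)
                loss = dice_loss(probs, patchify(mask.astype(np.float64), grid))
                batch_loss = loss if batch_loss is None else batch_loss + loss
            batch_loss = batch_loss * (1.0 / len(batch))
            check_finite(float(batch_loss.data), "segmentation fine-tuning")
            batch_loss.backward()
            opt.step()
            epoch_losses.append(float(batch_loss.data))
        mean_loss = float(np.mean(epoch_losses))
        history.append(mean_loss)
        if train_cfg.early_stop_patience > 0:
            if mean_loss < best - train_cfg.early_stop_min_delta:
                best = mean_loss
                stale = 0
            else:
                stale += 1
                if stale >= train_cfg.early_stop_patience:
                    break
    return params, history


def _resize_mask(mask: np.ndarray, target: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape == (target, target):
        return mask.astype(bool)
    return resize_normalize(mask.astype(np.float64), target) > 0.5


def evaluate(dataset, cfg: ModelConfig, params: dict
             ) -> tuple[float, list[dict]]:
    """Per-image hard Dice at threshold 0.5 and the unweighted mean."""
    table = []
    for i, (img, mask) in enumerate(dataset):
        pred = seg_forward(img, cfg, params)
        truth = _resize_mask(mask, cfg.image_size)
        res = dice_score(pred.binary_mask, truth)
        table.append({"index": i, "dice": res.dice,
                      "intersection": res.intersection,
                      "size_pred": res.size_pred, "size_truth": res.size_truth})
    mean_dice = float(np.mean([row["dice"] for row in table])) if table else float("nan")
    return mean_dice, table
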