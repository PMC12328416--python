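"""Masked-autoencoder pre-training with a visible-patch-weighted loss.

Training objective: 75% of patch tokens are masked at random; the encoder
sees only the visible 25%, the decoder restores full sequence length by
inserting a single shared learned mask token (plus positional information)
at the masked positions, and a linear head reconstructs raw pixel patches.
The reconstruction loss extends the classic masked-only objective with an
alpha-weighted term over the visible patches::

    loss = MSE(masked patches) + alpha * MSE(visible patches)

with alpha = 0.1 by default, so the model still attends to regions it was
shown while concentrating on in-painting the masked ones.  alpha = 0
recovers the original masked-autoencoder objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .patches import patchify, resize_normalize, tile_channels, unpatchify
from .training import AdamW, TrainConfig, augment_pair, check_finite, substream
from .transformer import (ModelConfig, decoder_forward, encoder_forward,
                          init_mae_params)

__all__ = ["MaskingResult", "MAELossConfig", "random_mask", "mae_forward",
           "mae_loss", "pretrain", "reconstruct_preview"]


@dataclass(frozen=True)
class MaskingResult:
    """A seeded partition of token indices into visible and masked sets."""

    visible_indices: np.ndarray
    masked_indices: np.ndarray
    restore_permutation: np.ndarray   # maps token id -> row in [visible; masked]
    mask_ratio: float

    @property
    def num_tokens(self) -> int:
        return self.visible_indices.size + self.masked_indices.size


@dataclass(frozen=True)
class MAELossConfig:
    alpha: float = 0.1
    normalize_targets: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def random_mask(L: int, r: float, seed) -> MaskingResult:
    """Uniformly mask ``round(r * L)`` of ``L`` tokens via a seeded shuffle."""
    if not (0.0 <= r < 1.0):
        raise ValueError(f"mask ratio must lie in [0, 1), got {r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_masked = int(np.floor(r * L + 0.5))
    perm = rng.permutation(L)
    visible = perm[: L - n_masked]
    masked = perm[L - n_masked:]
    order = np.concatenate([visible, masked])
    return MaskingResult(visible_indices=visible, masked_indices=masked,
                         restore_permutation=np.argsort(order), mask_ratio=r)


def _tile_rows(row: Tensor, n: int) -> Tensor:
    """Broadcast a (D,) parameter into an (n, D) block with gradient flow."""
    return Tensor(np.ones((n, 1))) @ row.reshape(1, -1)


def mae_forward(image: np.ndarray, mask: MaskingResult, cfg: ModelConfig,
                params: dict, return_aux: bool = False):
    """Reconstruct all patches from the visible subset.

    Only the visible tokens (with their positional entries) pass through
    the encoder; the decoder input is rebuilt to full length with the
    shared mask token standing in at masked positions, positional entries
    re-added, and the decoder output mapped back to pixel space.  Returns
    an ``(L, patch_dim * channels)`` Tensor (and an aux dict recording what
    the encoder consumed when ``return_aux``).
    """
    grid = cfg.grid
    if mask.num_tokens != grid.num_patches:
        raise ValueError(f"mask covers {mask.num_tokens} tokens but the grid "
                         f"has {grid.num_patches}")
    image = resize_normalize(image, cfg.image_size)
    raw = tile_channels(patchify(image, grid), cfg.channels)
    tokens = Tensor(raw) @ params["patch_embed.weight"] + params["patch_embed.bias"]
    tokens = tokens + params["pos_embed"]
    visible = tokens.gather_rows(mask.visible_indices)
    enc_final, _ = encoder_forward(visible, cfg, params)
    n_masked = mask.masked_indices.size
    if n_masked:
        full = concat([enc_final, _tile_rows(params["mask_token"], n_masked)], axis=0)
    else:
        full = enc_final
    restored = full.gather_rows(mask.restore_permutation)
    restored = restored + params["pos_embed"]
    dec = decoder_forward(restored, None, cfg, params,
                          n_layers=cfg.mae_decoder_layers, use_cross=False)
    recon = dec @ params["recon_head.weight"] + params["recon_head.bias"]
    if return_aux:
        aux = {"encoder_input_length": int(mask.visible_indices.size),
               "encoder_token_ids": mask.visible_indices.copy(),
               "target_patches": raw}
        return recon, aux
    return recon


def mae_loss(reconstructed, target_patches, mask: MaskingResult,
             cfg: MAELossConfig = MAELossConfig()):
    """Per-element MSE over masked rows plus alpha times the visible rows."""
    rec = reconstructed if isinstance(reconstructed, Tensor) else Tensor(reconstructed)
    target = np.asarray(target_patches, dtype=np.float64)
    if rec.shape != target.shape:
        raise ValueError(f"shape mismatch: reconstruction {rec.shape} vs "
                         f"target {target.shape}")
    if cfg.normalize_targets:
        mu = target.mean(axis=1, keepdims=True)
        sd = target.std(axis=1, keepdims=True)
        target = (target - mu) / (sd + 1e-6)
    if mask.masked_indices.size == 0 and cfg.alpha == 0:
        raise ValueError("loss undefined: no masked tokens and alpha = 0")
    total = None
    if mask.masked_indices.size:
        diff = rec.gather_rows(mask.masked_indices) - target[mask.masked_indices]
        total = (diff * diff).mean()
    if cfg.alpha > 0 and mask.visible_indices.size:
        diff = rec.gather_rows(mask.visible_indices) - target[mask.visible_indices]
        vis = (diff * diff).mean() * cfg.alpha
        total = vis if total is None else total + vis
    return total


def pretrain(dataset, cfg: ModelConfig, train_cfg: TrainConfig,
             mask_ratio: float = 0.75,
             loss_cfg: MAELossConfig = MAELossConfig(),
             params: dict | None = None) -> tuple[dict, list[float]]:
    """AdamW pre-training loop; returns (params, per-epoch mean losses).

    `dataset` is a sequence of grayscale images (mask halves of pairs are
    ignored).  Augmentation is horizontal flips plus random resized crops.
    All randomness derives from ``train_cfg.seed`` via named substreams.
    """
    images = [d[0] if isinstance(d, tuple) else d for d in dataset]
    if not images:
        raise ValueError("dataset is empty")
    if params is None:
        params = init_mae_params(cfg, substream(train_cfg.seed, "mae", "init"))
    opt = AdamW(params, train_cfg)
    L = cfg.num_patches
    history: list[float] = []
    for epoch in range(train_cfg.epochs):
        # per-epoch streams are a fixed function of the run seed, so a rerun
        # (and a zero-lr run) reproduces every batch exactly
        rng_order = substream(train_cfg.seed, "mae", "order")
        rng_mask = substream(train_cfg.seed, "mae", "mask")
        rng_aug = substream(train_cfg.seed, "mae", "augment")
        order = rng_order.permutation(len(images))
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            opt.zero_grad()
            batch_loss = None
            for idx in batch:
                img = resize_normalize(images[idx], cfg.image_size)
                if train_cfg.augment:
                    img, _ = augment_pair(img, None, train_cfg, rng_aug)
                mask = random_mask(L, mask_ratio, rng_mask)
                rec, aux = mae_forward(img, mask, cfg, params, return_aux=True)
                loss = mae_loss(rec, aux["target_patches"], mask, loss_cfg)
                batch_loss = loss if batch_loss is None else batch_loss + loss
            batch_loss = batch_loss * (1.0 / len(batch))
            check_finite(float(batch_loss.data), "MAE pre-training")
            batch_loss.backward()
            opt.step()
            epoch_losses.append(float(batch_loss.data))
        history.append(float(np.mean(epoch_losses)))
    return params, history


def reconstruct_preview(image: np.ndarray, mask: MaskingResult,
                        params: dict, cfg: ModelConfig) -> np.ndarray:
    """Side-by-side (original | masked input | reconstruction) panel."""
    grid = cfg.grid
    image = resize_normalize(image, cfg.image_size)
    raw = patchify(image, grid)
    masked_raw = raw.copy()
    masked_raw[mask.masked_indices] = 0.0
    rec = mae_forward(image, mask, cfg, params).data
    # average the replicated channel groups back to one gray channel
    rec_gray = rec.reshape(grid.num_patches, cfg.channels, grid.patch_dim).mean(axis=1)
    panels = [image, unpatchify(masked_raw, grid),
              np.clip(unpatchify(rec_gray, grid), 0.0, 1.0)]
    return np.concatenate(panels, axis=1)
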