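"""Shared training plumbing: seeded substreams, AdamW, data augmentation.

A single run seed fans out into named substreams (data order, masking,
augmentation, initialisation), so toggling one source of randomness never
perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = ["TrainConfig", "AdamW", "substream", "augment_pair"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Independent generator derived from `seed` and a stream name path."""
    keys = [zlib.crc32(n.encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


@dataclass
class TrainConfig:
    """Optimiser and loop settings.

    Published-scale settings are AdamW with lr 2e-5, batch 1,024 and 4,000
    epochs for masked-autoencoder pre-training, and lr 1.6e-4, batch 512,
    400 epochs for segmentation fine-tuning; every field here is
    configurable so desk-scale runs can shrink all of them.
    """

    epochs: int = 100
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 0.01
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    augment: bool = True
    flip_prob: float = 0.5
    crop_area: tuple[float, float] = (0.6, 1.0)
    rotate_deg: float = 15.0          # segmentation only
    use_rotation: bool = False
    grad_clip: float = 1.0            # global-norm clip; 0 disables
    lr_overrides: tuple = ()          # ((name_prefix, multiplier), ...)
    warmup_steps: int = 0             # linear lr warmup from 0
    total_steps: int = 0              # cosine decay horizon; 0 = constant lr
    early_stop_patience: int = 0      # 0 disables early stopping
    early_stop_min_delta: float = 1e-4
    seed: int = 0


class AdamW(object):
    """Decoupled-weight-decay Adam over a name -> Tensor parameter dict."""

    def __init__(self, params: dict, cfg: TrainConfig):
        self.params = params
        self.lr = cfg.lr
        self.beta1, self.beta2 = cfg.betas
        self.eps = cfg.eps
        self.weight_decay = cfg.weight_decay
        self.grad_clip = cfg.grad_clip
        self.warmup_steps = cfg.warmup_steps
        self.total_steps = cfg.total_steps
        self.lr_overrides = tuple(cfg.lr_overrides)
        self.t = 0
        self._m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self._v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def _clip(self) -> None:
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        norm = np.sqrt(total)
        if norm > self.grad_clip:
            scale = self.grad_clip / (norm + 1e-12)
            for p in self.params.values():
                if p.grad is not None:
                    p.grad *= scale

    def step(self) -> None:
        self.t += 1
        if self.grad_clip > 0:
            self._clip()
        lr_scale = min(1.0, self.t / self.warmup_steps) if self.warmup_steps else 1.0
        if self.total_steps > self.warmup_steps:
            frac = (max(self.t, self.warmup_steps) - self.warmup_steps) \
                / (self.total_steps - self.warmup_steps)
            lr_scale *= 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[k] = b1 * self._m[k] + (1 - b1) * p.grad
            v = self._v[k] = b2 * self._v[k] + (1 - b2) * p.grad ** 2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            mult = 1.0
            for prefix, m_ in self.lr_overrides:
                if k.startswith(prefix):
                    mult = m_
            p.data -= mult * lr_scale * self.lr * (update + self.weight_decay * p.data)


# ---------------------------------------------------------------------------
# augmentation (paired image/mask; mask may be None for MAE pre-training)
# ---------------------------------------------------------------------------

def augment_pair(image: np.ndarray, mask: np.ndarray | None,
                 cfg: TrainConfig, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Random flip, optional rotation, and random resized square crop.

    The same geometric transform is applied to image and mask; the mask is
    resampled nearest-neighbour so it stays binary.
    """
    img = image
    if rng.random() < cfg.flip_prob:
        img = img[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    if cfg.use_rotation and cfg.rotate_deg > 0:
        angle = rng.uniform(-cfg.rotate_deg, cfg.rotate_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="reflect")
        if mask is not None:
            mask = ndimage.rotate(mask.astype(np.float64), angle, reshape=False,
                                  order=0, mode="constant") > 0.5
    lo, hi = cfg.crop_area
    area = rng.uniform(lo, hi)
    size = img.shape[0]
    crop = max(4, int(round(size * np.sqrt(area))))
    r0 = int(rng.integers(0, size - crop + 1))
    c0 = int(rng.integers(0, size - crop + 1))
    img = img[r0:r0 + crop, c0:c0 + crop]
    img = np.clip(_sk_resize(img, (size, size), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True), 0.0, 1.0)
    if mask is not None:
        m = mask[r0:r0 + crop, c0:c0 + crop].astype(np.float64)
        mask = _sk_resize(m, (size, size), order=0, mode="edge",
                          anti_aliasing=False, preserve_range=True) > 0.5
    return np.ascontiguousarray(img), mask


def check_finite(loss_value: float, context: str) -> None:
    if not np.isfinite(loss_value):
        raise FloatingPointError(f"non-finite loss during {context}: {loss_value!r}")
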