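"""Image <-> token-sequence plumbing: resize, patchify, embed, assemble.

All functions here are deterministic numpy transforms.  ``patchify`` /
``unpatchify`` form an exact bijection on pixels: patch ``k`` of a
``g x g`` grid covers the rectangle at grid position ``(k // g, k % g)``
and is flattened row-major.  Coordinates are row-major and 0-based
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "PatchGrid",
    "resize_normalize",
    "patchify",
    "unpatchify",
    "build_positional_table",
    "embed_patches",
    "working_resolution",
]


def working_resolution(patch_size: int, target: int = 224) -> int:
    """Largest multiple of `patch_size` not exceeding `target`.

    224 is the nominal working resolution; patch sizes that do not divide
    it (e.g. 9) round the resolution down (216 = 24 * 9) so the patch
    tiling stays an exact bijection.
    """
    if patch_size < 1 or patch_size > target:
        raise ValueError(f"patch_size {patch_size} incompatible with target {target}")
    return (target // patch_size) * patch_size


@dataclass(frozen=True)
class PatchGrid:
    """Square patch tiling of a square image.

    ``patch_dim`` is the per-patch pixel count p*p for the single-channel
    raw patches this module produces; models may tile channels on top.
    """

    image_size: int
    patch_size: int

    def __post_init__(self) -> None:
        if self.image_size <= 0 or self.patch_size <= 0:
            raise ValueError("image_size and patch_size must be positive")
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"patch_size {self.patch_size} does not divide image_size "
                f"{self.image_size}; pick a compatible working resolution "
                f"(e.g. 216 for 9x9 patches)"
            )

    @property
    def grid_side(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_side ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size ** 2


def resize_normalize(image: np.ndarray, target: int) -> np.ndarray:
    """Return a float64 ``target x target`` image in [0, 1].

    8-bit inputs are scaled by 1/255.  Resizing is bilinear; an input that
    is already ``target x target`` is passed through untouched, so the
    operation is idempotent.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError(f"expected non-empty 2-D grayscale image, got shape {image.shape}")
    if image.dtype == np.uint8:
        image = image.astype(np.float64) / 255.0
    else:
        image = image.astype(np.float64)
    if image.shape == (target, target):
        return image
    out = _sk_resize(image, (target, target), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def patchify(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Split the image into ``(num_patches, patch_dim)`` row-major patches."""
    image = np.asarray(image)
    if image.shape != (grid.image_size, grid.image_size):
        raise ValueError(f"image shape {image.shape} does not match grid "
                         f"({grid.image_size}x{grid.image_size})")
    g, p = grid.grid_side, grid.patch_size
    x = image.reshape(g, p, g, p)
    return x.transpose(0, 2, 1, 3).reshape(grid.num_patches, grid.patch_dim)


def unpatchify(raw_patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`patchify`."""
    raw_patches = np.asarray(raw_patches)
    if raw_patches.shape != (grid.num_patches, grid.patch_dim):
        raise ValueError(f"expected {(grid.num_patches, grid.patch_dim)} patch "
                         f"array, got {raw_patches.shape}")
    g, p = grid.grid_side, grid.patch_size
    x = raw_patches.reshape(g, g, p, p).transpose(0, 2, 1, 3)
    return x.reshape(grid.image_size, grid.image_size)


def build_positional_table(L: int, D: int) -> np.ndarray:
    """Deterministic sine-cosine positional table of shape (L, D).

    For a perfect-square ``L`` the table is the 2-D factorisation used by
    masked-autoencoder ViTs: half the width encodes the row coordinate,
    half the column, each as interleaved sin/cos over geometrically spaced
    frequencies (requires ``D % 4 == 0``).  Otherwise a 1-D table over the
    flat index is returned.  Entries lie in [-1, 1]; rows are pairwise
    distinct.  The table carries no trainable state; models that learn
    positions use it as their initial value.
    """
    if L < 1 or D < 1:
        raise ValueError("L and D must be >= 1")
    if D % 2 != 0:
        raise ValueError(f"embedding width must be even, got {D}")
    side = int(round(np.sqrt(L)))
    if side * side == L and D % 4 == 0:
        half = D // 2
        rows = np.repeat(np.arange(side), side).astype(np.float64)
        cols = np.tile(np.arange(side), side).astype(np.float64)
        return np.concatenate([_sincos_1d(rows, half), _sincos_1d(cols, half)], axis=1)
    return _sincos_1d(np.arange(L, dtype=np.float64), D)


def _sincos_1d(pos: np.ndarray, width: int) -> np.ndarray:
    half = width // 2
    freqs = 1.0 / (10000.0 ** (np.arange(half, dtype=np.float64) / half))
    angles = pos[:, None] * freqs[None, :]
    return np.concatenate([np.sin(angles), np.cos(angles)], axis=1)


def embed_patches(raw_patches: np.ndarray, weight: np.ndarray,
                  bias: np.ndarray, positional: np.ndarray) -> np.ndarray:
    """Linear-project raw patches and add positional entries.

    ``weight`` has shape (patch_dim * channels, D); grayscale patches are
    tiled across the channel groups before projection, matching a model
    that treats single-channel input as replicated RGB.
    """
    raw_patches = np.asarray(raw_patches, dtype=np.float64)
    in_dim = weight.shape[0]
    if in_dim % raw_patches.shape[1] != 0:
        raise ValueError(f"weight input width {in_dim} incompatible with "
                         f"patch_dim {raw_patches.shape[1]}")
    channels = in_dim // raw_patches.shape[1]
    tiled = tile_channels(raw_patches, channels)
    tokens = tiled @ weight + bias
    if positional is not None:
        if positional.shape != tokens.shape:
            raise ValueError(f"positional table shape {positional.shape} does "
                             f"not match tokens {tokens.shape}")
        tokens = tokens + positional
    return tokens


def tile_channels(raw_patches: np.ndarray, channels: int) -> np.ndarray:
    """Replicate single-channel patch rows into ``channels`` groups."""
    if channels == 1:
        return raw_patches
    return np.tile(raw_patches, (1, channels))
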