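"""Synthetic B-mode-like ultrasound phantoms with ground-truth nodule masks.

Real thyroid ultrasound is characterised by granular multiplicative speckle,
low contrast between anatomical structures, and nodules of variable,
indistinct outline.  This module emulates those salient features with a
first-order model so the whole pre-training / segmentation pipeline can be
exercised and tested without any external dataset:

* a single hypoechoic (darker-than-background) nodule per image, whose
  boundary is a star-convex harmonic perturbation of a circle,
* fully developed multiplicative speckle modelled as unit-mean
  gamma-distributed noise, smoothed by a Gaussian point-spread function.

It is not an acoustic simulation: there is no beam propagation, attenuation
or log-compression, and no claim of TI-RADS-level realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "NoduleSpec",
    "SpeckleSpec",
    "generate_nodule_mask",
    "render_speckle_image",
    "generate_dataset",
    "load_manifest",
]


@dataclass(frozen=True)
class NoduleSpec:
    """Geometry and echogenicity of one nodule.

    The boundary in polar coordinates about ``center`` is
    ``r(theta) = base_radius * (1 + sum_i a_i * cos(f_i * theta + phi_i))``
    with harmonics ``(a_i, f_i, phi_i)``; amplitudes are fractions of the
    base radius and must sum to < 0.5 so the boundary stays star-convex
    (hence a single connected region).  ``echogenicity_contrast`` in
    [-1, 0) makes the nodule darker than the surrounding tissue.
    """

    center: tuple[float, float]
    base_radius: float
    boundary_harmonics: tuple[tuple[float, int, float], ...] = ()
    echogenicity_contrast: float = -0.5

    def __post_init__(self) -> None:
        if self.base_radius < 4.0:
            raise ValueError(f"base_radius must be >= 4 px, got {self.base_radius}")
        amp_sum = sum(a for a, _, _ in self.boundary_harmonics)
        if amp_sum >= 0.5:
            raise ValueError(f"sum of harmonic amplitudes must be < 0.5, got {amp_sum}")
        if not (-1.0 <= self.echogenicity_contrast < 0.0):
            raise ValueError("echogenicity_contrast must lie in [-1, 0)")

    @property
    def max_radius(self) -> float:
        return self.base_radius * (1.0 + sum(a for a, _, _ in self.boundary_harmonics))


@dataclass(frozen=True)
class SpeckleSpec:
    """Background level, multiplicative-noise shape, PSF blur and seed."""

    background_level: float = 0.55
    speckle_shape: float = 4.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.background_level < 1.0):
            raise ValueError("background_level must lie in (0, 1)")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")


def generate_nodule_mask(spec: NoduleSpec, height: int, width: int) -> np.ndarray:
    """Rasterise the nodule of `spec` into a boolean (height, width) mask.

    Pixel (r, c) is foreground iff its polar radius about the center is at
    most the harmonic boundary radius at that angle.  Raises ``ValueError``
    if the nodule's bounding box does not fit inside the image.
    """
    cr, cc = spec.center
    m = spec.max_radius
    if cr - m < 0 or cc - m < 0 or cr + m > height - 1 or cc + m > width - 1:
        raise ValueError(
            f"nodule (center={spec.center}, max radius {m:.1f}) exceeds "
            f"{height}x{width} image bounds"
        )
    rows = np.arange(height)[:, None] - cr
    cols = np.arange(width)[None, :] - cc
    rho = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    boundary = np.full_like(rho, spec.base_radius)
    for a, f, phi in spec.boundary_harmonics:
        boundary += spec.base_radius * a * np.cos(f * theta + phi)
    return rho <= boundary


def render_speckle_image(mask: np.ndarray, nodule: NoduleSpec,
                         speckle: SpeckleSpec) -> np.ndarray:
    """Render a [0,1] grayscale phantom: speckled tissue with a dark nodule.

    ``image = clip(blur(tissue * noise), 0, 1)`` where tissue equals the
    background level outside the mask and ``background * (1 + contrast)``
    inside, and noise is i.i.d. unit-mean Gamma(speckle_shape).
    """
    mask = np.asarray(mask, dtype=bool)
    tissue = np.where(mask,
                      speckle.background_level * (1.0 + nodule.echogenicity_contrast),
                      speckle.background_level)
    rng = np.random.default_rng(speckle.seed)
    noise = rng.gamma(shape=speckle.speckle_shape,
                      scale=1.0 / speckle.speckle_shape, size=mask.shape)
    img = ndimage.gaussian_filter(tissue * noise, sigma=speckle.blur_sigma)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

#: Sampling ranges for random phantoms, as fractions of image size where
#: geometric.  Chosen to yield plausibly low-contrast, irregular hypoechoic
#: nodules that remain clearly learnable at desk scale.
DEFAULT_RANGES: dict = {
    "radius_frac": (0.10, 0.22),        # base radius / image size
    "center_margin": 0.05,              # extra margin beyond max radius
    "n_harmonics": (2, 4),              # inclusive
    "harmonic_freq": (2, 6),            # inclusive, integer cycles
    "harmonic_amp_total": (0.15, 0.45),
    "contrast": (-0.65, -0.35),
    "background": (0.45, 0.65),
    "speckle_shape": (3.0, 8.0),
    "blur_sigma": (0.8, 1.5),
}


def _sample_specs(rng: np.random.Generator, image_size: int,
                  image_seed: int) -> tuple[NoduleSpec, SpeckleSpec]:
    R = DEFAULT_RANGES
    radius = image_size * rng.uniform(*R["radius_frac"])
    n_h = int(rng.integers(R["n_harmonics"][0], R["n_harmonics"][1] + 1))
    total_amp = rng.uniform(*R["harmonic_amp_total"])
    raw = rng.uniform(0.2, 1.0, size=n_h)
    amps = raw / raw.sum() * total_amp
    harmonics = tuple(
        (float(a),
         int(rng.integers(R["harmonic_freq"][0], R["harmonic_freq"][1] + 1)),
         float(rng.uniform(0.0, 2.0 * np.pi)))
        for a in amps
    )
    max_r = radius * (1.0 + total_amp)
    margin = max_r + R["center_margin"] * image_size
    lo, hi = margin, image_size - 1 - margin
    center = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
    nodule = NoduleSpec(center=center, base_radius=float(radius),
                        boundary_harmonics=harmonics,
                        echogenicity_contrast=float(rng.uniform(*R["contrast"])))
    speckle = SpeckleSpec(background_level=float(rng.uniform(*R["background"])),
                          speckle_shape=float(rng.uniform(*R["speckle_shape"])),
                          blur_sigma=float(rng.uniform(*R["blur_sigma"])),
                          seed=image_seed)
    return nodule, speckle


def _to_png(path: Path, array01: np.ndarray) -> None:
    Image.fromarray(np.round(array01 * 255.0).astype(np.uint8), mode="L").save(path)


def render_pair(nodule: NoduleSpec, speckle: SpeckleSpec,
                image_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Render (image, boolean mask) for one phantom."""
    mask = generate_nodule_mask(nodule, image_size, image_size)
    return render_speckle_image(mask, nodule, speckle), mask


def generate_dataset(n: int, image_size: int, seed: int, out_dir) -> dict:
    """Write `n` paired image/mask PNGs plus a JSON manifest; reproducible.

    Layout: ``out_dir/images/img_####.png`` (8-bit grayscale) and
    ``out_dir/masks/img_####.png`` ({0, 255}, foreground = 255).  The
    manifest records every sampled spec, so the corpus can be re-rendered
    exactly.  Returns the manifest as a dict.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    entries = []
    for i in range(n):
        image_seed = int(rng.integers(0, 2**31 - 1))
        nodule, speckle = _sample_specs(rng, image_size, image_seed)
        img, mask = render_pair(nodule, speckle, image_size)
        stem = f"img_{i:04d}"
        _to_png(out_dir / "images" / f"{stem}.png", img)
        _to_png(out_dir / "masks" / f"{stem}.png", mask.astype(np.float64))
        entries.append({
            "stem": stem,
            "nodule": {
                "center": list(nodule.center),
                "base_radius": nodule.base_radius,
                "boundary_harmonics": [list(h) for h in nodule.boundary_harmonics],
                "echogenicity_contrast": nodule.echogenicity_contrast,
            },
            "speckle": asdict(speckle),
        })
    manifest = {"n": n, "image_size": image_size, "seed": seed, "entries": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_manifest(out_dir) -> dict:
    with open(Path(out_dir) / "manifest.json") as fh:
        return json.load(fh)


def specs_from_manifest_entry(entry: dict) -> tuple[NoduleSpec, SpeckleSpec]:
    nd = entry["nodule"]
    nodule = NoduleSpec(center=tuple(nd["center"]),
                        base_radius=nd["base_radius"],
                        boundary_harmonics=tuple(tuple(h) for h in nd["boundary_harmonics"]),
                        echogenicity_contrast=nd["echogenicity_contrast"])
    return nodule, SpeckleSpec(**entry["speckle"])
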