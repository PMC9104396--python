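"""Seeded phantom generators: dermoscopy-like lesions (optionally with
synthetic hair occlusions) and dental-panoramic-like tooth rows, each with
exact ground-truth masks.

The phantoms are deliberately minimal: the contract is statistical (a dark
irregular blob on a textured skin-tone background; bright rounded teeth on
a darker jaw band), not photorealistic.  Identical seeds yield bit-identical
datasets, which makes every downstream module testable without external
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["SyntheticSpec", "make_lesion", "make_tooth", "make_dataset"]


@dataclass
class SyntheticSpec:
    kind: str = "lesion"
    n_images: int = 8
    size: tuple = (256, 256)
    lesion_area_range: tuple = (0.05, 0.3)
    hair: bool = False
    hair_count_range: tuple = (3, 8)
    noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("lesion", "tooth"):
            raise ValueError("kind must be 'lesion' or 'tooth'")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")


def _rng(spec, index):
    return np.random.default_rng([int(spec.seed), int(index)])


def _skin_background(rng, H, W, noise_sigma):
    base = np.array([0.78, 0.60, 0.50])
    img = np.ones((H, W, 3)) * base
    texture = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=H / 24)
    img += 0.05 * texture[..., None]
    img += noise_sigma * rng.standard_normal((H, W, 3))
    return img


def _lesion_mask(rng, H, W, area_range):
    """Irregular blob: ellipse with seeded radial boundary perturbation."""
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(64):
        frac = rng.uniform(*area_range)
        R = np.sqrt(frac * H * W / np.pi)
        cy = rng.uniform(0.38, 0.62) * H
        cx = rng.uniform(0.38, 0.62) * W
        elong = rng.uniform(0.75, 1.3)
        n_modes = 5
        amps = rng.uniform(0.0, 0.07, n_modes)
        phases = rng.uniform(0, 2 * np.pi, n_modes)
        dy, dx = (yy - cy) / elong, (xx - cx) * elong
        rho = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        r_theta = R * (
            1.0
            + sum(a * np.cos((m + 2) * theta + p) for m, (a, p) in enumerate(zip(amps, phases)))
        )
        mask = rho < r_theta
        mask = ndimage.binary_fill_holes(
            ndimage.gaussian_filter(mask.astype(float), sigma=1.5) > 0.5
        )
        got = mask.mean()
        if area_range[0] <= got <= area_range[1] and mask.any():
            return mask
    raise RuntimeError("could not sample a lesion mask within the area range")


def _draw_hairs(rng, img, count_range):
    """Overlay dark curvilinear strokes 1-3 px wide; returns their raster."""
    H, W = img.shape[:2]
    n = int(rng.integers(count_range[0], count_range[1] + 1))
    raster = np.zeros((H, W), dtype=bool)
    for _ in range(n):
        # quadratic Bezier across the frame
        p0 = rng.uniform([0, -0.2 * W], [H, 0]) if rng.random() < 0.5 else rng.uniform(
            [-0.2 * H, 0], [0, W]
        )
        p2 = rng.uniform([0, W], [H, 1.2 * W]) if rng.random() < 0.5 else rng.uniform(
            [H, 0], [1.2 * H, W]
        )
        p1 = rng.uniform([0, 0], [H, W])
        t = np.linspace(0, 1, 4 * max(H, W))
        curve = (
            np.outer((1 - t) ** 2, p0) + np.outer(2 * (1 - t) * t, p1) + np.outer(t ** 2, p2)
        )
        iy = np.clip(np.round(curve[:, 0]).astype(int), 0, H - 1)
        ix = np.clip(np.round(curve[:, 1]).astype(int), 0, W - 1)
        inside = (curve[:, 0] >= 0) & (curve[:, 0] < H) & (curve[:, 1] >= 0) & (curve[:, 1] < W)
        stroke = np.zeros((H, W), dtype=bool)
        stroke[iy[inside], ix[inside]] = True
        width = int(rng.integers(1, 4))
        if width > 1:
            stroke = ndimage.binary_dilation(stroke, iterations=width - 1)
        raster |= stroke
    shade = rng.uniform(0.12, 0.3)
    img[raster] = img[raster] * shade
    return raster


def make_lesion(spec: SyntheticSpec, index: int):
    """One lesion phantom: (image, mask, clean_image, hair_truth)."""
    if spec.kind != "lesion":
        raise ValueError("spec.kind must be 'lesion'")
    rng = _rng(spec, index)
    H, W = spec.size
    img = _skin_background(rng, H, W, spec.noise_sigma)
    mask = _lesion_mask(rng, H, W, spec.lesion_area_range)
    lesion_color = np.array([0.36, 0.22, 0.18]) + rng.uniform(-0.05, 0.05, 3)
    alpha = ndimage.gaussian_filter(mask.astype(float), sigma=2.0)
    alpha = np.clip(alpha, 0, 1)[..., None]
    img = (1 - alpha) * img + alpha * (
        lesion_color + spec.noise_sigma * rng.standard_normal((H, W, 3))
    )
    img = np.clip(img, 0.02, 1.0)
    clean = img.copy()
    hair_truth = np.zeros((H, W), dtype=bool)
    if spec.hair:
        hair_truth = _draw_hairs(rng, img, spec.hair_count_range)
    img = np.clip(img, 0.0, 1.0)
    return img, mask, clean, hair_truth


def make_tooth(spec: SyntheticSpec, index: int):
    """One dental phantom: (image, mask); mask components == tooth count."""
    if spec.kind != "tooth":
        raise ValueError("spec.kind must be 'tooth'")
    rng = _rng(spec, index)
    H, W = spec.size
    yy, xx = np.mgrid[0:H, 0:W]
    img = np.full((H, W), 0.15)
    band_c = H * rng.uniform(0.45, 0.55)
    band_h = H * 0.22
    band = np.exp(-0.5 * ((yy - band_c) / band_h) ** 2)
    img += 0.2 * band
    n_teeth = int(rng.integers(8, 15))
    spacing = W / (n_teeth + 1)
    half_w = spacing * rng.uniform(0.28, 0.38)
    mask = np.zeros((H, W), dtype=bool)
    for i in range(n_teeth):
        cx = spacing * (i + 1) + rng.uniform(-0.05, 0.05) * spacing
        cy = band_c + rng.uniform(-0.1, 0.1) * band_h
        ry = H * rng.uniform(0.10, 0.14)
        tooth = ((yy - cy) / ry) ** 2 + ((xx - cx) / half_w) ** 2 < 1.0
        mask |= tooth
    img = np.where(mask, 0.75 + 0.1 * band, img)
    img += spec.noise_sigma * rng.standard_normal((H, W))
    img = np.clip(img, 0.0, 1.0)
    n_found = ndimage.label(mask)[1]
    if n_found != n_teeth:  # overlapping jitter; deterministic fallback
        raise RuntimeError("tooth components merged; adjust spacing")
    return np.repeat(img[..., None], 3, axis=-1), mask


def make_dataset(spec: SyntheticSpec, out_dir):
    """Write n_images (image, mask) PNG pairs plus a JSON manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(spec.n_images):
        if spec.kind == "lesion":
            img, mask, clean, hair = make_lesion(spec, i)
            extra = {"lesion_fraction": float(mask.mean()), "hair_fraction": float(hair.mean())}
        else:
            img, mask = make_tooth(spec, i)
            extra = {"tooth_count": int(ndimage.label(mask)[1])}
        iname, mname = f"image_{i:03d}.png", f"mask_{i:03d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out / iname)
        Image.fromarray((mask.astype(np.uint8) * 255)).save(out / mname)
        entries.append({"index": i, "image": iname, "mask": mname, **extra})
    manifest = {"spec": asdict(spec), "images": entries}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
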