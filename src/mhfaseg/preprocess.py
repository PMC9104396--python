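"""Dermoscopic preprocessing: contrast enhancement, hair removal and
gray-shade color constancy.

The chain mirrors common dermoscopy practice: CLAHE on the luminance
channel improves local contrast; thin dark hairs are located with black
top-hat transforms using linear structuring elements at several
orientations; detected hair pixels are removed and re-filled by iterative
morphological (dilation) propagation from their unmasked neighbours; and a
gray-world ("gray shade") correction equalizes the channel means.  All
stages preserve shape and the [0, 1] intensity range and are deterministic
for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, draw, exposure, morphology

__all__ = [
    "PreprocessConfig",
    "HairMask",
    "enhance_contrast",
    "detect_hair_mask",
    "inpaint_hair",
    "gray_shade",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``clahe_clip`` is scikit-image's contrast clip limit; the mild default
    (0.005, with 8 tiles per side) corresponds to the standard conservative
    CLAHE setting used on dermoscopy and keeps local texture from being
    amplified into false hair responses.  ``se_length`` and
    ``se_orientations`` shape the linear structuring elements of the hair
    detector (15 px at 8 orientations suits 1-3 px wide hairs).
    ``hair_threshold`` is ``"otsu"`` or a fixed response threshold; Otsu is
    floored at ``response_floor`` so hair-free images yield empty masks.
    """

    clahe_clip: float = 0.005
    clahe_tile: int = 8
    se_length: int = 15
    se_orientations: int = 8
    hair_threshold: object = "otsu"
    dilate_radius: int = 1
    inpaint_max_iter: int = 100
    response_floor: float = 0.3

    def __post_init__(self):
        if self.se_orientations < 4:
            raise ValueError("se_orientations must be >= 4")
        if self.inpaint_max_iter < 1:
            raise ValueError("inpaint_max_iter must be positive")


@dataclass
class HairMask:
    mask: np.ndarray
    coverage_fraction: float


def _check_rgb(img):
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB image, got shape {img.shape}")
    return img


def enhance_contrast(img, cfg: PreprocessConfig = None):
    """CLAHE on the LAB luminance channel; chroma is preserved."""
    cfg = cfg or PreprocessConfig()
    img = _check_rgb(img)
    if img.std() < 1e-12:
        return img.copy()
    lab = color.rgb2lab(img)
    lum = lab[..., 0] / 100.0
    kernel = max(8, img.shape[0] // cfg.clahe_tile)
    eq = exposure.equalize_adapthist(
        np.clip(lum, 0, 1), kernel_size=kernel, clip_limit=cfg.clahe_clip
    )
    lab[..., 0] = eq * 100.0
    out = color.lab2rgb(lab)
    return np.clip(out, 0.0, 1.0)


def _linear_footprints(length, n_orientations):
    """Linear structuring elements of the given length at evenly spaced angles."""
    feet = []
    c = length // 2
    for i in range(n_orientations):
        theta = np.pi * i / n_orientations
        dy, dx = np.sin(theta), np.cos(theta)
        r0 = int(round(c - dy * (length - 1) / 2)), int(round(c - dx * (length - 1) / 2))
        r1 = int(round(c + dy * (length - 1) / 2)), int(round(c + dx * (length - 1) / 2))
        fp = np.zeros((length, length), dtype=bool)
        rr, cc = draw.line(r0[0], r0[1], r1[0], r1[1])
        fp[np.clip(rr, 0, length - 1), np.clip(cc, 0, length - 1)] = True
        feet.append(fp)
    return feet


def detect_hair_mask(img, cfg: PreprocessConfig = None) -> HairMask:
    """Locate thin dark curvilinear structures (hairs).

    Black top-hat responses with linear structuring elements are computed per
    channel and orientation, max-combined, thresholded and dilated.  An empty
    mask is a valid result.
    """
    cfg = cfg or PreprocessConfig()
    img = _check_rgb(img)
    response = np.zeros(img.shape[:2])
    for fp in _linear_footprints(cfg.se_length, cfg.se_orientations):
        for ch in range(3):
            th = morphology.black_tophat(img[..., ch], footprint=fp)
            np.maximum(response, th, out=response)
    if cfg.hair_threshold == "otsu":
        from skimage.filters import threshold_otsu

        if response.max() <= cfg.response_floor:
            thr = np.inf
        else:
            thr = max(threshold_otsu(response), cfg.response_floor)
    else:
        thr = float(cfg.hair_threshold)
    mask = response > thr
    if cfg.dilate_radius > 0 and mask.any():
        mask = ndimage.binary_dilation(
            mask, structure=morphology.disk(cfg.dilate_radius)
        )
    return HairMask(mask=mask, coverage_fraction=float(mask.mean()))


def inpaint_hair(img, mask, cfg: PreprocessConfig = None):
    """Fill masked pixels by iterative grey-dilation from unmasked neighbours.

    Unmasked pixels are returned unchanged (exactly).  Raises if the mask
    covers the whole image, since there is nothing to propagate from.
    """
    cfg = cfg or PreprocessConfig()
    img = _check_rgb(img)
    if isinstance(mask, HairMask):
        mask = mask.mask
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask and image spatial dimensions differ")
    if mask.all():
        raise ValueError("mask covers the entire image; nothing to inpaint from")
    if not mask.any():
        return img.copy()
    out = img.copy()
    known = ~mask
    vals = out.copy()
    vals[mask] = -1.0
    fp = np.ones((3, 3), dtype=bool)
    for _ in range(cfg.inpaint_max_iter):
        if known.all():
            break
        grown = ndimage.binary_dilation(known, structure=fp)
        newly = grown & ~known
        for ch in range(3):
            d = ndimage.grey_dilation(vals[..., ch], footprint=fp)
            vals[newly, ch] = d[newly]
        known = grown
    out[mask] = np.clip(vals[mask], 0.0, 1.0)
    return out


def gray_shade(img):
    """Gray-world constancy: rescale each channel mean to the global mean."""
    img = _check_rgb(img)
    means = img.reshape(-1, 3).mean(axis=0)
    if np.any(means < 1e-12):
        raise ValueError("zero-mean channel: gray-world gain undefined")
    target = means.mean()
    out = img * (target / means)
    return np.clip(out, 0.0, 1.0)


def preprocess_pipeline(img, cfg: PreprocessConfig = None, kind="skin"):
    """Full chain: CLAHE -> hair mask -> inpainting -> gray shade.

    Dental radiographs bypass the chain (``kind='dental'``); the hair and
    color-constancy model only applies to dermoscopy.
    Returns ``(image, HairMask)``.
    """
    cfg = cfg or PreprocessConfig()
    img = _check_rgb(img)
    if kind == "dental":
        return img.copy(), HairMask(np.zeros(img.shape[:2], bool), 0.0)
    enhanced = enhance_contrast(img, cfg)
    hair = detect_hair_mask(enhanced, cfg)
    filled = inpaint_hair(enhanced, hair, cfg)
    return gray_shade(filled), hair
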