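"""Joint image/mask augmentation: center crop, random 90-degree rotation,
grid distortion and horizontal/vertical flips.

Every transform is sampled once per pair and applied identically to the
image (bilinear resampling) and its mask (nearest-neighbour, so masks stay
strictly binary).  Augmentation is applied offline: a dataset is expanded
by an integer factor, with the originals always included, and is bit-exact
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "AugmentSpec",
    "augment_pair",
    "augment_dataset",
    "hflip",
    "vflip",
    "rot90k",
    "center_crop_resize",
    "grid_distort",
    "sample_grid_displacement",
]


@dataclass
class AugmentSpec:
    crop_fraction: float = 0.9
    rot90_choices: tuple = (0, 90, 180, 270)
    grid_limit: float = 0.3
    grid_cells: int = 5
    flip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.crop_fraction <= 1.0):
            raise ValueError("crop_fraction must be in (0, 1]")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ValueError("flip_prob must be in [0, 1]")


# ----- deterministic primitives (image or mask) --------------------------


def hflip(a):
    return np.ascontiguousarray(a[:, ::-1])


def vflip(a):
    return np.ascontiguousarray(a[::-1])


def rot90k(a, k):
    """Rotate by k * 90 degrees in the image plane."""
    return np.ascontiguousarray(np.rot90(a, k, axes=(0, 1)))


def center_crop_resize(a, fraction, is_mask=False):
    """Crop the central ``fraction`` of the frame and resize back."""
    if fraction >= 1.0:
        return a.copy()
    H, W = a.shape[:2]
    ch, cw = max(1, int(round(H * fraction))), max(1, int(round(W * fraction)))
    y0, x0 = (H - ch) // 2, (W - cw) // 2
    crop = a[y0 : y0 + ch, x0 : x0 + cw]
    out = resize(
        crop.astype(float),
        (H, W) + a.shape[2:],
        order=0 if is_mask else 1,
        preserve_range=True,
        anti_aliasing=False,
    )
    return (out > 0.5).astype(a.dtype) if is_mask else out


def sample_grid_displacement(rng, shape, cells, limit):
    """Node displacements (in pixels) for an n x n cell distortion grid."""
    H, W = shape[:2]
    nodes = cells + 1
    dy = rng.uniform(-limit, limit, size=(nodes, nodes)) * (H / cells)
    dx = rng.uniform(-limit, limit, size=(nodes, nodes)) * (W / cells)
    # pin the border nodes so the field stays inside the frame
    for d in (dy, dx):
        d[0, :] = d[-1, :] = d[:, 0] = d[:, -1] = 0.0
    return dy, dx


def grid_distort(a, displacement, is_mask=False):
    """Warp with a smooth displacement field interpolated from grid nodes."""
    dy_nodes, dx_nodes = displacement
    H, W = a.shape[:2]
    zoom = (H / dy_nodes.shape[0], W / dy_nodes.shape[1])
    dy = ndimage.zoom(dy_nodes, zoom, order=1)
    dx = ndimage.zoom(dx_nodes, zoom, order=1)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    coords = np.array([yy + dy, xx + dx])
    order = 0 if is_mask else 1
    if a.ndim == 2:
        out = ndimage.map_coordinates(a.astype(float), coords, order=order, mode="reflect")
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(a[..., c].astype(float), coords, order=order, mode="reflect")
                for c in range(a.shape[2])
            ],
            axis=-1,
        )
    return (out > 0.5).astype(a.dtype) if is_mask else out


# ----- joint sampling -----------------------------------------------------


def augment_pair(img, mask, spec: AugmentSpec, rng=None):
    """Apply one jointly sampled composition of the transforms to both tensors."""
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask)
    if img.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image and mask dims differ: {img.shape[:2]} vs {mask.shape[:2]}"
        )
    rng = rng if rng is not None else np.random.default_rng(spec.seed)

    img = center_crop_resize(img, spec.crop_fraction)
    mask = center_crop_resize(mask, spec.crop_fraction, is_mask=True)

    k = int(rng.choice(len(spec.rot90_choices)))
    quarter = spec.rot90_choices[k] // 90
    img, mask = rot90k(img, quarter), rot90k(mask, quarter)

    if spec.grid_limit > 0:
        disp = sample_grid_displacement(rng, img.shape, spec.grid_cells, spec.grid_limit)
        img = grid_distort(img, disp)
        mask = grid_distort(mask, disp, is_mask=True)

    if rng.random() < spec.flip_prob:
        img, mask = hflip(img), hflip(mask)
    if rng.random() < spec.flip_prob:
        img, mask = vflip(img), vflip(mask)

    img = np.clip(img, 0.0, 1.0)
    mask = (np.asarray(mask) > 0.5).astype(np.uint8)
    return img, mask


def augment_dataset(pairs, spec: AugmentSpec, factor: int):
    """Expand ``pairs`` by an integer factor.

    The originals are always included; copies are generated with
    independent, reproducible streams keyed on (seed, image index, copy
    index).  Output count is ``len(pairs) * factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    out = []
    for i, (img, mask) in enumerate(pairs):
        out.append((np.asarray(img, dtype=float), (np.asarray(mask) > 0.5).astype(np.uint8)))
        for j in range(1, factor):
            rng = np.random.default_rng([spec.seed, i, j])
            out.append(augment_pair(img, mask, spec, rng=rng))
    return out
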