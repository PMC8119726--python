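"""Dataset-specific preprocessing: dermoscopy, fundus, MR volumes, patches.

Dermoscopy images of any size are bilinearly rescaled to 192 x 256.  Fundus
images are cropped to the field-of-view bounding box and contrast-enhanced
per channel with CLAHE, then cut into 128 x 128 patches (stride 64 for
training, 128 for testing) that are later restitched to full images for
scoring.  MR cases are center-cropped in-plane, stacked as (T2, FLAIR, T1Gd)
three-channel slices, min-max normalized per volume and modality, and only
slices with nonzero labels enter training (all slices are evaluated).  Every
pipeline output lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import exposure, transform

__all__ = [
    "PatchGrid",
    "VolumeCase",
    "prep_dermoscopy",
    "prep_fundus",
    "extract_patches",
    "reconstruct",
    "prep_brats",
]

DERMOSCOPY_SHAPE = (192, 256)
PATCH_SIZE = 128
#: skimage CLAHE defaults: 8x8 tile grid, normalized clip limit
CLAHE_CLIP_LIMIT = 0.02
CLAHE_TILES = 8

BRATS_CHANNEL_ORDER = ("T2", "FLAIR", "T1Gd")
BRATS_CROP = 192


@dataclass
class PatchGrid:
    """Row-major grid of half-open patch windows [r, r+size) x [c, c+size)."""

    patch_size: int
    stride: int
    origins: list[tuple[int, int]]
    source_shape: tuple[int, int]


@dataclass
class VolumeCase:
    """One multi-modality MR case: modality name -> 3-D array (H, W, S)."""

    modalities: dict[str, np.ndarray]
    labels: np.ndarray

    def __post_init__(self):
        shapes = {m.shape for m in self.modalities.values()}
        if len(shapes) != 1:
            raise ValueError("all modalities must share one shape")
        if self.labels.shape != next(iter(shapes)):
            raise ValueError("labels must match the modality shape")

    @property
    def selected_slices(self) -> list[int]:
        """Indices of slices containing any nonzero label."""
        return [int(s) for s in range(self.labels.shape[2])
                if np.any(self.labels[:, :, s])]

    @property
    def whole_tumor(self) -> np.ndarray:
        return (self.labels > 0).astype(np.uint8)


def _rescale01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img, dtype=np.float64)
    return (img.astype(np.float64) - lo) / (hi - lo)


def prep_dermoscopy(image: np.ndarray, mask: np.ndarray,
                    out_shape=DERMOSCOPY_SHAPE):
    """Bilinear rescale of a dermoscopy image and its mask to 192 x 256.

    The mask is resized with the same interpolation and re-binarized at 0.5;
    image values are normalized to [0, 1].  An already-correctly-sized pair
    passes through pixel-identically (up to the [0,1] normalization).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    m = np.asarray(mask, dtype=np.float64)
    if m.max() > 1.0:
        m = m / 255.0
    if set(np.unique(m)) - {0.0, 1.0}:
        warnings.warn("non-binary mask input; thresholding at 0.5",
                      RuntimeWarning, stacklevel=2)
    if img.shape[:2] != tuple(out_shape):
        img = transform.resize(img, out_shape, order=1, anti_aliasing=False,
                               preserve_range=True)
        m = transform.resize(m, out_shape, order=1, anti_aliasing=False,
                             preserve_range=True)
    return np.clip(img, 0.0, 1.0), (m >= 0.5).astype(np.uint8)


def fov_bounding_box(fov_mask: np.ndarray) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) half-open bounding box of the FOV."""
    fov = np.asarray(fov_mask).astype(bool)
    if not fov.any():
        raise ValueError("empty field-of-view mask")
    rows = np.flatnonzero(fov.any(axis=1))
    cols = np.flatnonzero(fov.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def prep_fundus(image: np.ndarray, fov_mask: np.ndarray,
                clip_limit: float = CLAHE_CLIP_LIMIT,
                tiles: int = CLAHE_TILES):
    """FOV-bounding-box crop + per-channel CLAHE + [0,1] normalization.

    Returns (enhanced image, cropped FOV mask, bounding box).  Constant
    images pass through CLAHE unchanged (there is no contrast to equalize).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    fov = np.asarray(fov_mask).astype(bool)
    if img.shape[:2] != fov.shape:
        raise ValueError("image and FOV mask sizes differ")
    box = fov_bounding_box(fov)
    r0, r1, c0, c1 = box
    img = img[r0:r1, c0:c1]
    fov = fov[r0:r1, c0:c1]
    if img.ndim == 2:
        img = img[..., None]
    out = np.empty_like(img)
    kernel = (max(img.shape[0] // tiles, 1), max(img.shape[1] // tiles, 1))
    for ch in range(img.shape[2]):
        plane = img[..., ch]
        if plane.max() == plane.min():
            out[..., ch] = plane
        else:
            out[..., ch] = exposure.equalize_adapthist(
                _rescale01(plane), kernel_size=kernel, clip_limit=clip_limit)
    out = np.clip(out, 0.0, 1.0)
    if out.shape[2] == 1:
        out = out[..., 0]
    return out, fov.astype(np.uint8), box


def _axis_origins(length: int, patch: int, stride: int) -> list[int]:
    origins = list(range(0, length - patch + 1, stride))
    if origins[-1] != length - patch:
        origins.append(length - patch)  # final window anchored to the edge
    return origins


def extract_patches(image: np.ndarray, patch_size: int = PATCH_SIZE,
                    stride: int = 64):
    """Cut an image into a row-major grid of square patches.

    Returns (patches array (n, patch, patch[, C]), PatchGrid).  Every pixel
    is covered by at least one patch for stride <= patch_size; when the
    stride does not tile exactly, a final row/column of patches is anchored
    to the image edge.
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch size {patch_size} exceeds image {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be positive")
    origins = [(r, c) for r in _axis_origins(h, patch_size, stride)
               for c in _axis_origins(w, patch_size, stride)]
    patches = np.stack([img[r:r + patch_size, c:c + patch_size]
                        for r, c in origins])
    return patches, PatchGrid(patch_size, stride, origins, (h, w))


def reconstruct(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Restitch patches onto the source canvas, averaging any overlaps.

    Exact inverse of :func:`extract_patches` for full-coverage grids
    (bit-identical when the grid does not overlap).
    """
    h, w = grid.source_shape
    extra = patches.shape[3:]
    acc = np.zeros((h, w) + extra, dtype=np.float64)
    cnt = np.zeros((h, w) + (1,) * len(extra), dtype=np.float64)
    p = grid.patch_size
    for patch, (r, c) in zip(patches, grid.origins):
        acc[r:r + p, c:c + p] += patch
        cnt[r:r + p, c:c + p] += 1.0
    if (cnt == 0).any():
        raise ValueError("grid does not cover the full source image")
    out = acc / cnt
    return out.astype(patches.dtype) if patches.dtype.kind in "ui" else out


def prep_brats(case: VolumeCase, crop: int | None = BRATS_CROP,
               training: bool = True):
    """Slice a multi-modality MR case into 3-channel images + tumor masks.

    In-plane center crop to ``crop`` x ``crop`` (None disables), channels
    stacked as (T2, FLAIR, T1Gd), per-volume min-max normalization per
    modality.  With ``training=True`` only labeled slices are returned (a
    warning is issued when there are none); otherwise all slices, in order,
    so predictions can be re-stacked into a scorable volume.
    Returns (list of (H x W x 3 image, H x W binary mask), slice indices).
    """
    missing = [m for m in BRATS_CHANNEL_ORDER if m not in case.modalities]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    vol = {m: _rescale01(np.asarray(case.modalities[m], dtype=np.float64))
           for m in BRATS_CHANNEL_ORDER}
    labels = case.whole_tumor
    h, w, _ = labels.shape
    if crop is not None:
        if crop > h or crop > w:
            raise ValueError(f"crop {crop} exceeds in-plane size {h}x{w}")
        r0, c0 = (h - crop) // 2, (w - crop) // 2
        vol = {m: v[r0:r0 + crop, c0:c0 + crop] for m, v in vol.items()}
        labels = labels[r0:r0 + crop, c0:c0 + crop]
    indices = case.selected_slices if training else list(range(labels.shape[2]))
    if training and not indices:
        warnings.warn("volume has no labeled slices; empty training set",
                      RuntimeWarning, stacklevel=2)
    pairs = []
    for s in indices:
        img = np.stack([vol[m][:, :, s] for m in BRATS_CHANNEL_ORDER], axis=-1)
        pairs.append((img, labels[:, :, s]))
    return pairs, indices
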