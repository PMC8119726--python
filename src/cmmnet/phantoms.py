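"""Seeded synthetic phantoms emulating the three imaging tasks.

These generators provide exact ground truth by construction, so every
pipeline stage — preprocessing, training, inversion recovery, metrics — is
testable offline and deterministically.  ``lesion`` phantoms emulate
dermoscopy: a single irregular dark blob on a textured skin-like background
with optional hair-like strokes.  ``vessel`` phantoms emulate fundus images:
a branching tree of thin curves inside a circular field of view.
``tumor_volume`` phantoms emulate multi-modality MR cases: four correlated
pseudo-modalities with a bright irregular 3-D blob spanning a contiguous
slab of slices.

All randomness flows through ``numpy.random.Generator(PCG64(seed))``, a
single portable RNG, so identical specs produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .data_pipelines import VolumeCase

__all__ = ["PhantomSpec", "make_lesion", "make_vessels", "make_tumor_volume",
           "make_lesion_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "lesion"
    size: tuple = (192, 256)
    difficulty: str = "easy"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("lesion", "vessel", "tumor_volume"):
            raise ValueError(f"unknown phantom kind: {self.kind}")
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")


def _rng(spec: PhantomSpec) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(spec.seed))


def _irregular_blob(shape, center, radii, rng, n_harmonics=6, roughness=0.25):
    """Filled polar-perturbed ellipse: r(theta) = r0 * (1 + Fourier noise)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - center[0]) / radii[0]
    dx = (xx - center[1]) / radii[1]
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bump = np.zeros_like(theta)
    for k in range(1, n_harmonics + 1):
        amp = roughness * rng.normal() / k
        phase = rng.uniform(0, 2 * np.pi)
        bump += amp * np.cos(k * theta + phase)
    return rad <= 1.0 + bump


def make_lesion(spec: PhantomSpec):
    """A dermoscopy-style phantom: (H x W x 3 image in [0,1], binary mask)."""
    rng = _rng(spec)
    h, w = spec.size
    hard = spec.difficulty == "hard"
    center = (h / 2 + rng.uniform(-0.12, 0.12) * h,
              w / 2 + rng.uniform(-0.12, 0.12) * w)
    radii = (rng.uniform(0.14, 0.30) * h, rng.uniform(0.14, 0.30) * w)
    mask = _irregular_blob((h, w), center, radii, rng,
                           roughness=0.35 if hard else 0.2)

    skin = np.array([0.80, 0.62, 0.55])
    lesion = np.array([0.38, 0.26, 0.22])
    img = np.empty((h, w, 3))
    img[:] = skin
    img[mask] = lesion
    # smooth boundary + low-frequency illumination + pixel noise
    img = ndimage.gaussian_filter(img, sigma=(2.0, 2.0, 0))
    illum = ndimage.gaussian_filter(rng.normal(0, 1.0, (h, w)), sigma=h / 6)
    img += 0.05 * illum[..., None]
    img += rng.normal(0, 0.05 if hard else 0.02, img.shape)

    n_hairs = rng.integers(6, 14) if hard else rng.integers(0, 3)
    for _ in range(n_hairs):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 0.9) * min(h, w)
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
        rr, cc = draw.line(r0, c0, r1, c1)
        img[rr, cc] *= 0.35
    return np.clip(img, 0.0, 1.0), mask.astype(np.uint8)


def make_vessels(spec: PhantomSpec):
    """A fundus-style phantom: (image, vessel mask, FOV mask).

    The vessel tree is grown recursively from a seed point; every stroke
    starts at a pixel of its parent, so the tree is a single 8-connected
    component, and all vessel pixels lie inside the circular FOV.
    """
    rng = _rng(spec)
    h, w = spec.size
    cy, cx = h / 2, w / 2
    fov_r = 0.47 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= fov_r ** 2

    mask = np.zeros((h, w), dtype=bool)

    def grow(pos, direction, width, depth):
        length = int(rng.uniform(0.12, 0.25) * min(h, w))
        path = [pos]
        d = direction
        for _ in range(length):
            d = d + rng.normal(0, 0.15)
            nxt = (path[-1][0] + np.sin(d), path[-1][1] + np.cos(d))
            if (nxt[0] - cy) ** 2 + (nxt[1] - cx) ** 2 >= (fov_r - width - 1) ** 2:
                break
            path.append(nxt)
        for y, x in path:
            # integer centers: a radius-0.5 disk always covers its pixel, so
            # unit steps yield an 8-connected stroke
            rr, cc = draw.disk((round(y), round(x)), max(width / 2, 0.5),
                               shape=(h, w))
            mask[rr, cc] = True
        if depth > 0 and len(path) > 3:
            tip = path[-1]
            for sign in (-1, 1):
                grow(tip, d + sign * rng.uniform(0.3, 0.8),
                     max(width - 1, 1), depth - 1)

    start = (cy + rng.uniform(-0.1, 0.1) * h, cx + rng.uniform(-0.1, 0.1) * w)
    grow(start, rng.uniform(0, 2 * np.pi), 4, depth=4)
    mask &= fov

    base = np.array([0.72, 0.45, 0.28])  # fundus-orange background
    img = np.empty((h, w, 3))
    img[:] = base
    tex = ndimage.gaussian_filter(rng.normal(0, 1.0, (h, w)), sigma=3)
    img += 0.04 * tex[..., None]
    img[mask] = np.array([0.30, 0.12, 0.10])
    img = ndimage.gaussian_filter(img, sigma=(0.6, 0.6, 0))
    noise_sd = 0.04 if spec.difficulty == "hard" else 0.015
    img += rng.normal(0, noise_sd, img.shape)
    img[~fov] = 0.02
    return np.clip(img, 0.0, 1.0), mask.astype(np.uint8), fov.astype(np.uint8)


def make_tumor_volume(spec: PhantomSpec = PhantomSpec(kind="tumor_volume",
                                                      size=(64, 64, 24))):
    """An MR-style phantom case with four correlated pseudo-modalities.

    The tumor is a perturbed ellipsoid confined to a contiguous slab of
    slices; labels mark exactly the tumor voxels.
    """
    rng = _rng(spec)
    h, w, s = spec.size
    slab_len = max(3, int(rng.uniform(0.3, 0.6) * s))
    slab_start = int(rng.integers(1, s - slab_len))
    center = (h / 2 + rng.uniform(-0.1, 0.1) * h,
              w / 2 + rng.uniform(-0.1, 0.1) * w,
              slab_start + slab_len / 2)
    radii = (rng.uniform(0.12, 0.2) * h, rng.uniform(0.12, 0.2) * w,
             slab_len / 2)
    zz, yy, xx = np.mgrid[0:h, 0:w, 0:s]
    dist = ((zz - center[0]) / radii[0]) ** 2 + \
           ((yy - center[1]) / radii[1]) ** 2 + \
           ((xx - center[2]) / radii[2]) ** 2
    wobble = ndimage.gaussian_filter(rng.normal(0, 1.0, (h, w, s)), sigma=4)
    tumor = dist <= 1.0 + 0.3 * wobble
    tumor[:, :, :slab_start] = False
    tumor[:, :, slab_start + slab_len:] = False

    # brain-like shared anatomy + per-modality contrast
    anatomy = ndimage.gaussian_filter(rng.normal(0.5, 0.15, (h, w, s)), sigma=3)
    brain = (zz - h / 2) ** 2 + (yy - w / 2) ** 2 <= (0.45 * min(h, w)) ** 2
    noise_sd = 0.06 if spec.difficulty == "hard" else 0.02
    gains = {"T1": -0.1, "T1Gd": 0.45, "T2": 0.5, "FLAIR": 0.6}
    modalities = {}
    for name, gain in gains.items():
        vol = 0.2 + 0.5 * anatomy
        vol[~brain] = 0.05
        vol[tumor] += gain
        vol += rng.normal(0, noise_sd, vol.shape)
        modalities[name] = np.clip(vol, 0.0, 1.5)
    return VolumeCase(modalities=modalities,
                      labels=tumor.astype(np.int16))


def make_lesion_dataset(n: int, size=(64, 64), difficulty="easy", seed=0):
    """A list of n seeded lesion phantoms (image, mask)."""
    return [make_lesion(PhantomSpec(kind="lesion", size=tuple(size),
                                    difficulty=difficulty, seed=seed + i))
            for i in range(n)]
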