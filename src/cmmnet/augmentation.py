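"""The eight-member geometric augmentation family and color-space variants.

The "eight times" augmentation is the dihedral group D4: four rotations
(0/90/180/270 degrees) optionally composed with a horizontal flip.  The same
transforms drive training augmentation and the inversion-recovery test-time
scheme, so each element knows its exact inverse (bit-exact on any array).

For dermoscopy, LAB and SV color-space copies of the RGB data are used as
additional training samples; SV (2 channels) is stacked as (S, V, V) to keep
the 3-channel network interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

__all__ = ["GeomTransform", "DIHEDRAL_GROUP", "eightfold", "color_variants"]


@dataclass(frozen=True)
class GeomTransform:
    """rot90 applied ``rotation``/90 times after an optional horizontal flip."""

    rotation: int = 0
    horizontal_flip: bool = False

    def __post_init__(self):
        if self.rotation not in (0, 90, 180, 270):
            raise ValueError("rotation must be one of 0, 90, 180, 270")

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """Transform an H x W or H x W x C array (leading two axes spatial)."""
        out = arr
        if self.horizontal_flip:
            out = np.flip(out, axis=1)
        k = self.rotation // 90
        if k:
            out = np.rot90(out, k, axes=(0, 1))
        return np.ascontiguousarray(out)

    def inverse(self) -> "GeomTransform":
        if self.horizontal_flip:
            # flip-then-rotate elements are reflections: self-inverse
            return self
        return GeomTransform((360 - self.rotation) % 360, False)

    def compose(self, other: "GeomTransform") -> "GeomTransform":
        """The element equivalent to applying ``other`` first, then ``self``."""
        probe = np.arange(12, dtype=np.int64).reshape(3, 4)
        target = self.apply(other.apply(probe))
        for cand in DIHEDRAL_GROUP:
            if cand.apply(probe).shape == target.shape and \
                    np.array_equal(cand.apply(probe), target):
                return cand
        raise RuntimeError("group is not closed")  # pragma: no cover


DIHEDRAL_GROUP = tuple(GeomTransform(rot, flip)
                       for flip in (False, True)
                       for rot in (0, 90, 180, 270))


def eightfold(image: np.ndarray, mask: np.ndarray):
    """All 8 dihedral views of an (image, mask) pair.

    Returns a list of (image, mask, transform) triples whose first entry is
    the identity view; masks are transformed identically to images.  Applied
    to a training set this multiplies its size by eight (15,290 inputs give
    122,320 samples).
    """
    return [(t.apply(image), t.apply(mask), t) for t in DIHEDRAL_GROUP]


def color_variants(rgb: np.ndarray) -> dict[str, np.ndarray]:
    """RGB, rescaled LAB, and (S, V, V) renderings of an RGB image in [0,1]."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    lab = skcolor.rgb2lab(rgb)
    lab_scaled = np.stack([lab[..., 0] / 100.0,
                           (lab[..., 1] + 128.0) / 255.0,
                           (lab[..., 2] + 128.0) / 255.0], axis=-1)
    hsv = skcolor.rgb2hsv(rgb)
    sv = np.stack([hsv[..., 1], hsv[..., 2], hsv[..., 2]], axis=-1)
    return {"rgb": rgb,
            "lab": np.clip(lab_scaled, 0.0, 1.0),
            "sv": np.clip(sv, 0.0, 1.0)}
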