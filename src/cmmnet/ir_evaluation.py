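"""Inversion Recovery (IR): logical test-time augmentation.

Instead of averaging augmented predictions, IR binarizes each augmented
view's prediction, inverts it back to the original frame, and accumulates
the views with a pixelwise logical OR:

    I_o = I_o | IR(I_k),   k = 1..n.

When multiple color-space renderings are evaluated (dermoscopy), the
OR-merged map of each color space is combined across spaces with a logical
AND.  OR can only grow the foreground (the result is a superset of the
single-view prediction); AND keeps only pixels every color space agrees on.
IR is optional at evaluation time — on some tasks (irregular, fragmented
targets such as brain tumors) it can reduce performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augmentation import DIHEDRAL_GROUP, GeomTransform, color_variants

__all__ = ["IRPrediction", "ir_or_merge", "ir_and_merge", "run_ir"]


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    return m.astype(bool)


@dataclass
class IRPrediction:
    """A segmented original view plus recovered augmented views."""

    original: np.ndarray
    recovered: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        shape = np.asarray(self.original).shape
        for m in self.recovered:
            if np.asarray(m).shape != shape:
                raise ValueError("all IR views must share one shape")


def ir_or_merge(pred: IRPrediction) -> np.ndarray:
    """Pixelwise OR of the original view with all recovered views."""
    out = _as_binary(pred.original)
    for m in pred.recovered:
        out = out | _as_binary(m)
    return out.astype(np.uint8)


def ir_and_merge(masks) -> np.ndarray:
    """Pixelwise AND across per-color-space (already OR-merged) masks."""
    masks = list(masks)
    if not masks:
        raise ValueError("ir_and_merge needs at least one mask")
    shape = np.asarray(masks[0]).shape
    out = _as_binary(masks[0])
    for m in masks[1:]:
        if np.asarray(m).shape != shape:
            raise ValueError("masks must share one shape")
        out = out & _as_binary(m)
    return out.astype(np.uint8)


def run_ir(model, image: np.ndarray, transforms=DIHEDRAL_GROUP,
           threshold: float = 0.5, color_spaces=None,
           return_views: bool = False):
    """Full IR evaluation of one image.

    For every transform: transform the image, predict, binarize at
    ``threshold``, and map the mask back through the inverse transform; the
    views are OR-merged.  With ``color_spaces`` (subset of
    {"rgb", "lab", "sv"}), the OR merge runs per space and the per-space
    results are AND-merged.  ``model`` needs a
    ``predict_proba(image) -> H x W`` method.
    """
    if color_spaces:
        variants = color_variants(image)
        merged, views = [], {}
        for space in color_spaces:
            m, v = _run_ir_single(model, variants[space], transforms, threshold)
            merged.append(m)
            views[space] = v
        result = ir_and_merge(merged)
    else:
        result, views = _run_ir_single(model, image, transforms, threshold)
    if return_views:
        return result, views
    return result


def _run_ir_single(model, image, transforms, threshold):
    views = []
    for t in transforms:
        prob = model.predict_proba(t.apply(image))
        mask = (prob >= threshold).astype(np.uint8)
        views.append(t.inverse().apply(mask))
    identity_first = sorted(
        range(len(views)),
        key=lambda i: transforms[i] != GeomTransform(0, False))
    pred = IRPrediction(views[identity_first[0]],
                        [views[i] for i in identity_first[1:]])
    return ir_or_merge(pred), views
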