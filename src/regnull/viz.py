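"""Deformation-field overlays and difference-image rendering.

The overlay color-codes the x and y components of the displacement vector at
each pixel on top of the grayscale fixed image: positive/negative u_x tints
red/cyan, positive/negative u_y tints yellow/blue, with opacity scaled by
displacement magnitude.  Zero displacement leaves the background untouched,
so correctly-unmoved regions read as plain gray.  An optional white
rectangle outline marks the copied region.  The palette is purely
presentational and overridable.
"""

from __future__ import annotations

import numpy as np

from .registration import _check_field

__all__ = ["render_overlay", "normalize_difference"]

_POS_X = np.array([1.0, 0.1, 0.1])   # red
_NEG_X = np.array([0.0, 0.9, 0.9])   # cyan
_POS_Y = np.array([1.0, 0.9, 0.1])   # yellow
_NEG_Y = np.array([0.1, 0.2, 1.0])   # blue


def render_overlay(field, background, box=None, scale=None,
                   max_alpha: float = 0.75) -> np.ndarray:
    """Render a displacement field as a color tint over a grayscale image.

    Parameters
    ----------
    field : (H, W, 2) array
        Displacements; ``[..., 0]`` = u_x, ``[..., 1]`` = u_y.
    background : (H, W) array
        Grayscale image shown under the tint.
    box : (x0, y0, width, height) or None
        Optional rectangle outlined in white (the copied region).
    scale : float or None
        Displacement magnitude mapped to full opacity; defaults to the
        field's maximum component magnitude (or 1 for an all-zero field).

    Returns
    -------
    (H, W, 3) uint8 RGB image.
    """
    field = _check_field(field)
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim != 2 or bg.shape != field.shape[:2]:
        raise ValueError(
            f"background shape {bg.shape} != field grid {field.shape[:2]}"
        )
    span = bg.max() - bg.min()
    gray = (bg - bg.min()) / span if span > 0 else np.full_like(bg, 0.5)
    out = np.repeat(gray[..., None], 3, axis=2)

    if scale is None:
        scale = float(np.abs(field).max()) or 1.0
    ux = np.clip(field[..., 0] / scale, -1.0, 1.0)
    uy = np.clip(field[..., 1] / scale, -1.0, 1.0)

    tint = (
        np.clip(ux, 0, 1)[..., None] * _POS_X
        + np.clip(-ux, 0, 1)[..., None] * _NEG_X
        + np.clip(uy, 0, 1)[..., None] * _POS_Y
        + np.clip(-uy, 0, 1)[..., None] * _NEG_Y
    )
    weight = np.clip(np.abs(ux) + np.abs(uy), 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        tint = np.where(weight[..., None] > 0, tint / np.maximum(weight, 1e-12)[..., None], 0.0)
    alpha = max_alpha * np.minimum(np.hypot(ux, uy), 1.0)[..., None]
    out = (1.0 - alpha) * out + alpha * np.clip(tint, 0, 1)

    if box is not None:
        x0, y0, bw, bh = box
        x1, y1 = x0 + bw - 1, y0 + bh - 1
        h, w = out.shape[:2]
        xs = slice(max(x0, 0), min(x1 + 1, w))
        ys = slice(max(y0, 0), min(y1 + 1, h))
        for yy in (y0, y1):
            if 0 <= yy < h:
                out[yy, xs] = 1.0
        for xx in (x0, x1):
            if 0 <= xx < w:
                out[ys, xx] = 1.0

    return np.clip(np.rint(out * 255), 0, 255).astype(np.uint8)


def normalize_difference(diff) -> np.ndarray:
    """Display-normalize a signed difference image to uint8.

    Zero difference maps to mid-gray (128); the largest absolute difference
    maps to black/white symmetrically.  An all-zero difference renders as a
    uniform mid-gray frame.
    """
    diff = np.asarray(diff, dtype=np.float64)
    m = np.abs(diff).max()
    if m == 0:
        return np.full(diff.shape, 128, dtype=np.uint8)
    return np.clip(np.rint(128 + 127 * diff / m), 0, 255).astype(np.uint8)
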