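"""Projection and background correction.

The quantification pipeline always works on a single 2D image per channel:
z-stacks are reduced by an average-intensity projection (never a maximum
projection), and each channel is then background-corrected with one of two
selectable estimators of the smooth background:

``opening``
    grayscale morphological opening with a disk strictly larger than any
    cell ("rolling-ball"-style), subtracted from the image;
``polynomial``
    a low-order (<= 3) polynomial surface least-squares-fitted to the
    below-median pixels, subtracted from the image.

Corrected intensities are clipped at zero.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import disk, opening

from .errors import EmptyStackError, MitolocError, ShapeMismatchError

_MAX_FIT_PIXELS = 20000  # subsample cap for the polynomial fit


def average_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean across z-planes; a single plane passes through."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim != 3:
        raise ShapeMismatchError(f"expected a 2D plane or 3D stack, got ndim={arr.ndim}")
    if arr.shape[0] == 0:
        raise EmptyStackError("cannot project an empty z-stack")
    return arr.mean(axis=0)


def _poly_terms(y: np.ndarray, x: np.ndarray, order: int) -> np.ndarray:
    cols = [
        (x**i) * (y**j)
        for i in range(order + 1)
        for j in range(order + 1 - i)
    ]
    return np.stack(cols, axis=-1)


def _polynomial_background(image: np.ndarray, order: int) -> np.ndarray:
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    # normalize coordinates to [-1, 1] for a well-conditioned fit
    yn = 2 * yy / max(h - 1, 1) - 1
    xn = 2 * xx / max(w - 1, 1) - 1

    sel = image <= np.median(image)
    ys, xs, vs = yn[sel], xn[sel], image[sel]
    if ys.size > _MAX_FIT_PIXELS:
        step = ys.size // _MAX_FIT_PIXELS + 1
        ys, xs, vs = ys[::step], xs[::step], vs[::step]
    design = _poly_terms(ys, xs, order)
    coef, *_ = np.linalg.lstsq(design, vs, rcond=None)
    return _poly_terms(yn, xn, order) @ coef


def correct_background(
    image: np.ndarray,
    method: str = "opening",
    radius_px: int = 50,
    poly_order: int = 2,
) -> np.ndarray:
    """Subtract an estimated smooth background; result is clipped at 0."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ShapeMismatchError("background correction expects a 2D image")
    if img.size and img.min() < 0:
        raise MitolocError("background correction expects nonnegative intensities")

    if method == "opening":
        if 2 * radius_px + 1 > min(img.shape):
            raise MitolocError(
                f"structuring element (diameter {2 * radius_px + 1}) exceeds "
                f"image shape {img.shape}"
            )
        background = opening(img, disk(radius_px, decomposition="sequence"))
    elif method == "polynomial":
        if poly_order > 3:
            raise MitolocError("polynomial background order is limited to 3")
        background = _polynomial_background(img, poly_order)
    else:
        raise MitolocError(f"unknown background method {method!r}")

    return np.clip(img - background, 0.0, None)
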