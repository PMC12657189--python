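"""Mean-preserving linear contrast mathematics.

The core transform is the affine gray-level stretch

    I'(x, y) = alpha * (I(x, y) - mu) + mu,

where ``mu`` is the image mean and ``alpha > 0`` the contrast gain:
``alpha > 1`` stretches intensity deviations about the brightness
center, ``alpha < 1`` compresses them, and the image mean is preserved
exactly. Gains predicted by a network are squashed into the clinically
motivated open interval (1, 3) by ``map_to_contrast``. ``expand_views``
applies a whole vector of gains at once, producing the K x H x W view
stack that downstream classifiers consume; it accepts either numpy
arrays or autograd :class:`~acam._autograd.Tensor` inputs, so gradients
flow through both the pixels and the gains.

No clipping is applied anywhere in the transform path: values outside
[0, 1] are legal and keep the mapping differentiable. Clipping happens
only on raster export for display.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ._autograd import Tensor

__all__ = [
    "MIN_IMAGE_SIDE",
    "CONTRAST_LOW",
    "CONTRAST_HIGH",
    "image_mean",
    "apply_contrast",
    "map_to_contrast",
    "expand_views",
    "validate_image",
    "load_image",
    "save_views",
]

MIN_IMAGE_SIDE = 8
#: gain bounds of the mapping function; outputs lie in the OPEN interval
CONTRAST_LOW = 1.0
CONTRAST_HIGH = 3.0

# Rec. 601 luminance weights for color -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check the grayscale-image contract: 2-D, >= 8 pixels a side, finite."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape[0] < MIN_IMAGE_SIDE or img.shape[1] < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, got {img.shape}"
        )
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixel values")
    return img


def image_mean(img: np.ndarray) -> float:
    """Mean intensity mu = (1 / HW) sum_xy I(x, y), the brightness center."""
    return float(validate_image(img).mean())


def apply_contrast(img, alpha):
    """Linear contrast adjustment ``alpha * (I - mu) + mu``, out of place.

    Works on plain 2-D numpy images and on autograd tensors of shape
    (..., H, W); the mean is taken over the trailing two axes. The output
    mean equals the input mean and the standard deviation scales by
    ``alpha``. No clipping.
    """
    if isinstance(img, Tensor) or isinstance(alpha, Tensor):
        if isinstance(img, Tensor):
            mu = img.mean(axis=(-2, -1), keepdims=True)
        else:
            img = Tensor(img)
            mu = img.mean(axis=(-2, -1), keepdims=True)
        return alpha * (img - mu) + mu
    a = float(alpha)
    if not np.isfinite(a) or a <= 0:
        raise ValueError(f"contrast gain must be a positive finite number, got {alpha!r}")
    img = validate_image(img)
    mu = img.mean()
    return a * (img - mu) + mu


def map_to_contrast(x):
    """Bounded gain mapping ``1 + 2 / (1 + exp(-x))``.

    Strictly increasing with range the open interval (1, 3); applied
    elementwise to arrays. The midpoint maps a zero pre-activation to a
    gain of 2, the center of the clinical adjustment range.
    """
    if isinstance(x, Tensor):
        from ._autograd import sigmoid

        return 1.0 + 2.0 * sigmoid(x)
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("pre-activation input must be finite")
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    out = 1.0 + 2.0 * out
    return float(out) if out.ndim == 0 else out


def _validate_contrasts(contrasts: np.ndarray) -> np.ndarray:
    contrasts = np.atleast_1d(np.asarray(contrasts, dtype=np.float64))
    if contrasts.size == 0:
        raise ValueError("contrast vector must contain at least one gain")
    if not np.all(np.isfinite(contrasts)) or np.any(contrasts <= 0):
        raise ValueError("contrast gains must be positive and finite")
    return contrasts


def expand_views(img, contrasts):
    """Expand one image into a K x H x W stack of contrast-adjusted views.

    View ``k`` is ``apply_contrast(img, c_k)``. Every view shares the
    source image's mean. Tensor inputs keep the operation differentiable
    with respect to both pixels and gains; in that case ``img`` has shape
    (N, 1, H, W) and ``contrasts`` shape (N, K), giving (N, K, H, W).
    """
    if isinstance(img, Tensor) or isinstance(contrasts, Tensor):
        img_t = img if isinstance(img, Tensor) else Tensor(img)
        c_t = contrasts if isinstance(contrasts, Tensor) else Tensor(contrasts)
        mu = img_t.mean(axis=(-2, -1), keepdims=True)  # (N, 1, 1, 1)
        n, k = c_t.shape
        return c_t.reshape(n, k, 1, 1) * (img_t - mu) + mu
    img = validate_image(img)
    contrasts = _validate_contrasts(contrasts)
    mu = img.mean()
    return contrasts[:, None, None] * (img[None, :, :] - mu) + mu


# -- raster I/O -----------------------------------------------------------


def load_image(path) -> np.ndarray:
    """Read PNG/JPEG as a grayscale image on the canonical [0, 1] scale.

    Color inputs are collapsed with Rec. 601 luminance weights
    (0.299 R + 0.587 G + 0.114 B).
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return validate_image(arr / 255.0)


def save_views(stack: np.ndarray, contrasts, out_dir, stem: str = "view") -> list[Path]:
    """Export each view as an 8-bit PNG (display-clipped to [0, 1]).

    Writes ``<stem>_<k>.png`` per view plus a JSON sidecar listing the
    gains, and returns the image paths.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = np.asarray(stack, dtype=np.float64)
    paths = []
    for k in range(stack.shape[0]):
        view8 = (np.clip(stack[k], 0.0, 1.0) * 255.0).round().astype(np.uint8)
        p = out_dir / f"{stem}_{k:02d}.png"
        iio.imwrite(p, view8)
        paths.append(p)
    (out_dir / f"{stem}_contrasts.json").write_text(
        json.dumps({"contrasts": [float(c) for c in np.atleast_1d(contrasts)]}, indent=2)
    )
    return paths
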