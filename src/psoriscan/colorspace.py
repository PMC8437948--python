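"""Image/mask I/O and the color-space conversions used throughout the pipeline.

All conversions operate on ``uint8`` RGB arrays of shape ``(H, W, 3)``.
Lab uses the sRGB companding curve and the D65 reference white (the default
convention of every mainstream imaging toolchain); YCbCr uses full-range
(JPEG) BT.601 coefficients, so achromatic pixels map to ``Cb = Cr = 128``.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image
from skimage import color as _skcolor

__all__ = [
    "rgb_to_lab",
    "rgb_to_hsv",
    "rgb_to_ycbcr",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

# Full-range BT.601 RGB -> YCbCr matrix (JPEG convention).
_YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB intensities must lie in [0, 255]")
    return arr


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to CIE-L*a*b* (sRGB companding, D65 white).

    Returns a float array of the same shape with L* in [0, 100] and a*, b*
    roughly in [-128, 127].
    """
    arr = _validate_rgb(img)
    return _skcolor.rgb2lab(arr.astype(np.float64) / 255.0)


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert RGB to HSV with H in degrees [0, 360) and S, V in [0, 1].

    Achromatic pixels get the conventional H = 0.
    """
    arr = _validate_rgb(img)
    hsv = _skcolor.rgb2hsv(arr.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] * 360.0) % 360.0
    return hsv


def rgb_to_ycbcr(img: np.ndarray) -> np.ndarray:
    """Convert RGB to full-range BT.601 YCbCr (JPEG convention).

    Y, Cb, Cr are floats in [0, 255]; achromatic input maps to Cb = Cr = 128.
    """
    arr = _validate_rgb(img).astype(np.float64)
    out = arr @ _YCBCR_MATRIX.T
    out[..., 1] += 128.0
    out[..., 2] += 128.0
    return np.clip(out, 0.0, 255.0)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or JPEG image as an H x W x 3 uint8 RGB array."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | os.PathLike, img: np.ndarray) -> None:
    arr = _validate_rgb(img)
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG mask as a boolean array, binarized at 50% intensity."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:  # RGB(A) mask files: use luminance
        arr = np.asarray(Image.fromarray(arr).convert("L"))
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    limit = np.iinfo(arr.dtype).max if arr.dtype.kind == "u" else arr.max() or 1
    return arr.astype(np.float64) > 0.5 * float(limit)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG (foreground = 255)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    Image.fromarray(np.where(arr.astype(bool), 255, 0).astype(np.uint8)).save(path)
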