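"""Color-space transforms, per-channel normalization and ROI cropping.

The preprocessing contract shared by all experiments: images are read
as RGB in [0, 1], optionally transformed to HSV or YUV, normalized to
zero mean and unit standard deviation per channel, and (for equally
sized regions of interest) centrally cropped.

Conventions
-----------
* Hue is scaled to [0, 1] (angle / 360 deg) and treated as a *linear*
  coordinate afterwards; its circularity is not wrapped into the
  Chebyshev distance of the entropy measures.  This is a documented
  limitation.
* YUV uses the BT.601 luma coefficients (Y = 0.299 R + 0.587 G + 0.114 B).
* Normalization is per-channel by default because HSV/YUV channels live
  on incommensurate scales; a ``mode="global"`` switch normalizes the
  whole volume with one mean/SD instead.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color as _skcolor

from .image import ColorImage

__all__ = [
    "rgb_to_hsv", "hsv_to_rgb", "rgb_to_yuv", "yuv_to_rgb",
    "normalize_channels", "central_crop", "to_space",
]


def _require_rgb(img: ColorImage) -> None:
    if img.space.upper() != "RGB":
        raise ValueError(f"expected an RGB image, got space tag {img.space!r}")
    if img.n_channels != 3:
        raise ValueError("RGB image must have 3 channels")


def rgb_to_hsv(img: ColorImage) -> ColorImage:
    """Hexcone RGB -> HSV; input values must lie in [0, 1].

    H, S, V all land in [0, 1] (hue is the angle divided by 360 deg).
    """
    _require_rgb(img)
    if img.pixels.min() < 0.0 or img.pixels.max() > 1.0:
        raise ValueError("RGB values must lie in [0, 1] for HSV conversion")
    out = _skcolor.rgb2hsv(img.pixels)
    return ColorImage(out, space="HSV", labels=("H", "S", "V"))


def hsv_to_rgb(img: ColorImage) -> ColorImage:
    """Inverse hexcone transform (provided for round-trip testing)."""
    if img.space.upper() != "HSV":
        raise ValueError("expected an HSV image")
    out = _skcolor.hsv2rgb(img.pixels)
    return ColorImage(out, space="RGB", labels=("R", "G", "B"))


def rgb_to_yuv(img: ColorImage) -> ColorImage:
    """Linear BT.601 RGB -> YUV (Y luminance, U/V chrominance)."""
    _require_rgb(img)
    out = _skcolor.rgb2yuv(img.pixels)
    return ColorImage(out, space="YUV", labels=("Y", "U", "V"))


def yuv_to_rgb(img: ColorImage) -> ColorImage:
    """Inverse BT.601 transform (provided for round-trip testing)."""
    if img.space.upper() != "YUV":
        raise ValueError("expected a YUV image")
    out = _skcolor.yuv2rgb(img.pixels)
    return ColorImage(out, space="RGB", labels=("R", "G", "B"))


def to_space(img: ColorImage, space: str) -> ColorImage:
    """Convert an RGB image to ``space`` in {"rgb", "hsv", "yuv"}."""
    space = space.lower()
    if space == "rgb":
        return img
    if space == "hsv":
        return rgb_to_hsv(img)
    if space == "yuv":
        return rgb_to_yuv(img)
    raise ValueError(f"unknown color space {space!r}")


def normalize_channels(img: ColorImage, mode: str = "per-channel") -> ColorImage:
    """Subtract the mean and divide by the standard deviation.

    ``mode="per-channel"`` (default) standardizes each channel on its
    own; ``mode="global"`` uses one mean/SD for the whole volume.
    A zero-variance channel is legitimate (constant fixtures) and is
    passed through mean-subtracted only, with a warning, so downstream
    entropies come out 0 rather than NaN.
    """
    px = img.pixels
    if mode == "global":
        sd = px.std()
        if np.ptp(px) == 0.0:
            warnings.warn("constant image: normalization skipped the scaling step")
            return img.with_pixels(px - px.mean())
        return img.with_pixels((px - px.mean()) / sd)
    if mode != "per-channel":
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = np.empty_like(px)
    for k in range(img.n_channels):
        ch = px[:, :, k]
        sd = ch.std()
        if np.ptp(ch) == 0.0:  # exact constant test; std can round to ~1e-17
            warnings.warn(
                f"channel {img.labels[k]} has zero variance; mean-subtracted only")
            out[:, :, k] = ch - ch.mean()
        else:
            out[:, :, k] = (ch - ch.mean()) / sd
    return img.with_pixels(out)


def central_crop(img: ColorImage, side: int) -> ColorImage:
    """Extract the centered ``side x side`` region (all channels).

    For odd remainders the extra row/column is dropped from the
    bottom/right: the offset is floor((H - side) / 2) on each axis.
    """
    if side < 1:
        raise ValueError("side must be positive")
    if side > min(img.height, img.width):
        raise ValueError(
            f"crop side {side} exceeds image extent "
            f"{img.height}x{img.width}")
    r0 = (img.height - side) // 2
    c0 = (img.width - side) // 2
    return img.with_pixels(img.pixels[r0:r0 + side, c0:c0 + side, :])
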