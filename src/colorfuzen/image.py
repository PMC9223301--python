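"""The ColorImage container and image file I/O.

Every measure in this package consumes a :class:`ColorImage`: a
height x width x K grid of real-valued intensities together with a
color-space tag and channel labels.  K is 3 for color measures; K = 1
is allowed for single planes fed to the per-channel operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ColorImage", "read_image", "write_image"]


@dataclass(frozen=True)
class ColorImage:
    """An H x W x K stack of real-valued channels.

    Parameters
    ----------
    pixels
        Array of shape ``(H, W, K)`` (a 2-D array is promoted to K=1).
        Stored as float64; all values must be finite.
    space
        Color-space tag: ``"RGB"``, ``"HSV"``, ``"YUV"`` or ``"generic"``.
    labels
        Channel labels, one per channel (defaults K1..Kn).
    """

    pixels: np.ndarray
    space: str = "generic"
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3:
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        object.__setattr__(self, "pixels", px)
        labels = tuple(self.labels) or tuple(f"K{i + 1}" for i in range(px.shape[2]))
        if len(labels) != px.shape[2]:
            raise ValueError("one label per channel required")
        object.__setattr__(self, "labels", labels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, k: int) -> np.ndarray:
        """Return channel ``k`` (0-based) as a 2-D array."""
        return self.pixels[:, :, k]

    def with_pixels(self, pixels: np.ndarray, space: str | None = None,
                    labels: tuple[str, ...] | None = None) -> "ColorImage":
        return ColorImage(pixels,
                          space=self.space if space is None else space,
                          labels=self.labels if labels is None else labels)


def read_image(path) -> ColorImage:
    """Read a PNG/JPEG/TIFF file into a float RGB ColorImage.

    Integer images are rescaled by their dtype maximum to [0, 1]; float
    images are taken as-is.  An alpha channel is dropped; grayscale is
    kept as a single channel with tag "generic".
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 2:
        return ColorImage(arr, space="generic")
    if arr.shape[2] != 3:
        raise ValueError(f"expected 1, 3 or 4 channels, got {arr.shape[2]}")
    return ColorImage(arr, space="RGB", labels=("R", "G", "B"))


def write_image(path, img: ColorImage) -> None:
    """Write a ColorImage losslessly as a float32 TIFF.

    Float TIFF preserves negative values (normalized or MIX-process
    images are zero-mean), so no affine offset bookkeeping is needed.
    """
    import tifffile

    data = img.pixels.astype(np.float32)
    if data.shape[2] == 1:
        data = data[:, :, 0]
    tifffile.imwrite(str(path), data)


def read_float_tiff(path) -> ColorImage:
    """Read back a float TIFF written by :func:`write_image` (no rescale)."""
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    return ColorImage(arr, space="generic")
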