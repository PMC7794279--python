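"""Grayscale image container and PNG I/O.

A :class:`GrayImage` is the universal image currency of the package: a 2-D
luminance array with values nominally in [0, 1] plus a pixels-per-degree
scale factor that converts visual-field geometry (eccentricities, target
diameters, gaps, all specified in degrees) into pixels.  The default scale
of 30 px/deg reproduces the viewing geometry of the experiments the
package models; simulations may use a coarser scale to shrink images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

DEFAULT_PX_PER_DEG = 30.0


@dataclass
class GrayImage:
    """2-D luminance image with a visual-field scale.

    Parameters
    ----------
    pixels : ndarray
        Real-valued 2-D array, luminance in [0, 1] (values slightly outside
        the range are tolerated; NaN/inf are not).
    px_per_deg : float
        Pixels per degree of visual field, > 0.
    """

    pixels: np.ndarray
    px_per_deg: float = DEFAULT_PX_PER_DEG

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        h, w = self.pixels.shape
        if h < 32 or w < 32 or h % 2 or w % 2:
            raise ValueError(
                f"image dimensions must be even and >= 32, got {h}x{w}"
            )
        if not self.px_per_deg > 0:
            raise ValueError("px_per_deg must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def deg_to_px(self, deg: float) -> float:
        """Convert a visual-field extent in degrees to pixels."""
        return deg * self.px_per_deg

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.px_per_deg)


def read_png(path, px_per_deg: float = DEFAULT_PX_PER_DEG) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG, mapping linearly to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse trivial channel axes (e.g. RGB of a gray image)
        arr = arr[..., :3].mean(axis=-1)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        pixels = arr / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr / 65535.0
    else:
        pixels = arr.astype(np.float64)
    return GrayImage(pixels, px_per_deg)


def write_png(path, img: GrayImage, bitdepth: int = 16) -> None:
    """Write a GrayImage as a grayscale PNG (values clipped to [0, 1])."""
    clipped = np.clip(img.pixels, 0.0, 1.0)
    if bitdepth == 8:
        iio.imwrite(path, np.round(clipped * 255).astype(np.uint8))
    elif bitdepth == 16:
        iio.imwrite(path, np.round(clipped * 65535).astype(np.uint16))
    else:
        raise ValueError("bitdepth must be 8 or 16")
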