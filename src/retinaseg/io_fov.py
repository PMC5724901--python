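"""Loading fundus images, FOV mask generation and FOV border smoothing.

Image conventions used throughout the package:

* a *fundus image* is an ``(H, W, 3)`` uint8 array (RGB, 8 bit per channel);
* a *gray image* is an ``(H, W)`` float64 array with values in ``[0, 1]``;
* a *mask* (FOV, truth, segmentation) is an ``(H, W)`` bool array;
* coordinates are ``(row, col)``, 0-based; images and masks share the frame.
"""

from __future__ import annotations

import logging

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import color

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "DegenerateInputError",
    "load_fundus",
    "extract_green",
    "compute_fov_mask",
    "smooth_fov_border",
    "save_mask",
]


class FormatError(ValueError):
    """Raised when a file decodes to something other than an RGB image."""


class DegenerateInputError(ValueError):
    """Raised when an input is valid but carries no usable signal."""


def load_fundus(path) -> np.ndarray:
    """Load a color fundus image as an (H, W, 3) uint8 RGB array.

    16-bit sources are rescaled to 8 bit; an alpha channel, if present,
    is dropped.  Single-channel files raise :class:`FormatError`.
    """
    pixels = iio.imread(path)
    if pixels.ndim == 2:
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got 1 channel"
        )
    if pixels.ndim != 3 or pixels.shape[2] not in (3, 4):
        nchan = pixels.shape[2] if pixels.ndim == 3 else pixels.ndim
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got {nchan} channels"
        )
    if pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    if pixels.dtype == np.uint16:
        pixels = (pixels // 257).astype(np.uint8)
    elif pixels.dtype != np.uint8:
        pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    logger.info(
        "loaded %s: %dx%d, dtype %s", path, pixels.shape[0], pixels.shape[1],
        pixels.dtype,
    )
    return pixels


def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green channel scaled to [0, 1].

    The green channel carries the highest vessel/background contrast of the
    three RGB channels and is the working grayscale image for every
    downstream stage.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError("expected an (H, W, 3) RGB array")
    return img[:, :, 1].astype(np.float64) / 255.0


def compute_fov_mask(img: np.ndarray, luminance_threshold: float = 0.10) -> np.ndarray:
    """Estimate the circular field of view by thresholding CIELab luminance.

    The L channel (D65 illuminant, rescaled to [0, 1]) is thresholded;
    the largest 8-connected component is kept and its holes are filled, so
    the mask is a single connected component without holes.

    Raises
    ------
    DegenerateInputError
        If no pixel exceeds the threshold.
    """
    img = np.asarray(img)
    lum = color.rgb2lab(img.astype(np.float64) / 255.0)[:, :, 0] / 100.0
    raw = lum > luminance_threshold
    if not raw.any():
        raise DegenerateInputError(
            "FOV thresholding produced an empty mask; image may be all black"
        )
    labels, n = ndi.label(raw, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        raw = labels == np.argmax(sizes)
    return ndi.binary_fill_holes(raw)


_NEIGHBORS = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def smooth_fov_border(
    img: np.ndarray, mask: np.ndarray, iterations: int = 50
) -> np.ndarray:
    """Grow the FOV outward, filling each new rim pixel with its inside mean.

    Per iteration every pixel 8-adjacent to the current mask but outside it
    receives the mean of its 8-connected neighbors that are inside, and
    joins the mask.  Fifty iterations suppress the strong dark-to-bright
    transition at the FOV boundary that would otherwise produce false
    vessel responses.  Pixels strictly inside the original mask are never
    altered.
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(
            f"image shape {img.shape} != mask shape {mask.shape}"
        )
    out = img.copy()
    cur = mask.copy()
    for _ in range(int(iterations)):
        ring = ndi.binary_dilation(cur, structure=np.ones((3, 3), bool)) & ~cur
        if not ring.any():
            break
        ssum = ndi.convolve(out * cur, _NEIGHBORS, mode="constant", cval=0.0)
        cnt = ndi.convolve(cur.astype(float), _NEIGHBORS, mode="constant", cval=0.0)
        out[ring] = ssum[ring] / cnt[ring]
        cur |= ring
    return out


def save_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    iio.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))
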