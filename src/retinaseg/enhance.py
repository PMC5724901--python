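"""Denoising, contrast enhancement, Retinex inhomogeneity correction and
background removal.

Every stage maps a [0, 1] gray image to a [0, 1] gray image of the same
shape.  The default stage order follows the worked preprocessing chain:
median -> FOV border smoothing -> CLAHE -> Retinex -> morphological
enhancement -> background subtraction -> top-hat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology

__all__ = [
    "RetinexParams",
    "EnhanceConfig",
    "median_denoise",
    "clahe",
    "morph_enhance",
    "bilateral_filter",
    "retinex_reflectance",
    "estimate_background",
    "subtract_background",
    "final_tophat",
]


@dataclass(frozen=True)
class RetinexParams:
    """Bilateral-filter Retinex parameters.

    window_size : odd side of the filtering window, in pixels (default 3).
    sigma_d     : spread of the spatial closeness weight, in pixels.
    sigma_r     : spread of the intensity similarity weight, on the [0, 1]
                  intensity scale.  Both default to 0.3.
    """

    window_size: int = 3
    sigma_d: float = 0.3
    sigma_r: float = 0.3

    def __post_init__(self):
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if self.sigma_d <= 0 or self.sigma_r <= 0:
            raise ValueError("sigma_d and sigma_r must be positive")


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the unnumbered preprocessing stages.

    The clip limit / tile grid (CLAHE), structuring-element radii and the
    background median kernel are not pinned by the method description;
    defaults are conventional values that avoid noise amplification.
    """

    median_size: int = 3
    clahe_clip: float = 0.01
    clahe_tiles: tuple = (8, 8)
    open_radius: int = 1
    hat_radius: int = 4
    background_kernel: int = 25
    border_iterations: int = 50
    stage_order: tuple = (
        "median", "border", "clahe", "retinex", "morph", "background", "tophat",
    )
    retinex: RetinexParams = field(default_factory=RetinexParams)

    def __post_init__(self):
        if self.median_size % 2 == 0 or self.median_size < 1:
            raise ValueError("median_size must be odd and positive")
        if self.background_kernel % 2 == 0 or self.background_kernel < 1:
            raise ValueError("background_kernel must be odd and positive")


def _clip01(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, 1.0)


def median_denoise(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Median filter with edge replication; default 3x3."""
    if size % 2 == 0:
        raise ValueError("median filter size must be odd")
    return ndi.median_filter(np.asarray(img, float), size=size, mode="nearest")


def clahe(img: np.ndarray, clip: float = 0.01, tiles: tuple = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, output in [0, 1]."""
    if clip <= 0:
        raise ValueError("clip limit must be positive")
    img = _clip01(np.asarray(img, float))
    h, w = img.shape
    kernel = (max(1, h // tiles[0]), max(1, w // tiles[1]))
    return exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip)


def morph_enhance(img: np.ndarray, open_radius: int = 1, hat_radius: int = 4) -> np.ndarray:
    """Morphological opening followed by top-hat/bottom-hat enhancement.

    The image is opened with a disk of ``open_radius`` (noise reduction),
    then enhanced as ``clip01(opened + tophat(opened) - bottomhat(opened))``
    with a disk of ``hat_radius``.  For dark vessels on a bright background
    the bottom-hat term deepens the vessels, raising their contrast.
    """
    if open_radius <= 0 or hat_radius <= 0:
        raise ValueError("structuring-element radii must be positive")
    img = np.asarray(img, float)
    fp_open = morphology.disk(open_radius)
    fp_hat = morphology.disk(hat_radius)
    opened = ndi.grey_opening(img, footprint=fp_open, mode="reflect")
    top = opened - ndi.grey_opening(opened, footprint=fp_hat, mode="reflect")
    bottom = ndi.grey_closing(opened, footprint=fp_hat, mode="reflect") - opened
    return _clip01(opened + top - bottom)


def bilateral_filter(img: np.ndarray, p: RetinexParams = RetinexParams()) -> np.ndarray:
    """Edge-preserving illumination estimate L(x).

    ``L(x) = M(x)^-1 * sum_w I(l) g(l,x) s(l,x)`` over the window ``w``,
    where ``g`` weights spatial closeness (Euclidean pixel distance, spread
    sigma_d) and ``s`` weights intensity similarity (spread sigma_r);
    ``M`` normalizes the weights.  Borders are reflect-padded.
    """
    img = np.asarray(img, float)
    r = p.window_size // 2
    padded = np.pad(img, r, mode="reflect")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    h, w = img.shape
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            g = np.exp(-0.5 * (dy * dy + dx * dx) / p.sigma_d**2)
            s = np.exp(-0.5 * ((shifted - img) / p.sigma_r) ** 2)
            num += shifted * g * s
            den += g * s
    return num / den


def retinex_reflectance(
    img: np.ndarray,
    p: RetinexParams = RetinexParams(),
    fov: np.ndarray | None = None,
    rescale: bool = True,
) -> np.ndarray:
    """Retinex reflectance: log(I+1) - log(L+1) with L from the bilateral filter.

    The raw log-difference is a small signed field; by default it is
    min-max rescaled to [0, 1] (over the FOV when given) for the later
    stages.  A constant image yields an identically zero field.
    """
    img = np.asarray(img, float)
    if (img < 0).any():
        raise ValueError("retinex input must be non-negative")
    L = bilateral_filter(img, p)
    refl = np.log(img + 1.0) - np.log(L + 1.0)
    if not rescale:
        return refl
    region = refl[fov] if fov is not None else refl
    lo, hi = float(region.min()), float(region.max())
    if hi - lo < 1e-12:
        return np.zeros_like(refl)
    return _clip01((refl - lo) / (hi - lo))


def estimate_background(img: np.ndarray, kernel: int = 25) -> np.ndarray:
    """Smooth background estimate: median filter with a large kernel."""
    if kernel % 2 == 0:
        raise ValueError("background kernel must be odd")
    return ndi.median_filter(np.asarray(img, float), size=kernel, mode="nearest")


def subtract_background(img: np.ndarray, kernel: int = 25) -> np.ndarray:
    """Remove the smooth background, leaving vessels bright on ~0.

    The image is subtracted from its large-kernel median-filtered version
    (``clip01(median(img) - img)``): the flat background cancels while dark
    thin vessels, much narrower than the kernel, survive the median and come
    out bright.  ``kernel = 1`` is the identity median and yields a zero
    field.
    """
    return _clip01(estimate_background(img, kernel) - np.asarray(img, float))


def final_tophat(img: np.ndarray, hat_radius: int = 4) -> np.ndarray:
    """White top-hat keeping small bright structures (the vessels)."""
    img = np.asarray(img, float)
    fp = morphology.disk(hat_radius)
    return _clip01(img - ndi.grey_opening(img, footprint=fp, mode="reflect"))
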