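"""Pixel-wise texture features on the enhanced image.

Each pixel inside the FOV is described by 35 features computed on a small
sliding window centered on it (default 3x3, edge-replicated at borders):

* 4 intensity moments (raw central moments of order 1-4, not standardized);
* 22 gray-level co-occurrence (GLCM / Haralick) statistics, from one table
  pooled symmetrically over the four 45-degree multiples at a fixed distance;
* 7 gray-level run-length (GLRLM) statistics, pooled over the same four
  directions;
* 2 Gabor features (local squared energy and quadrature amplitude, averaged
  over orientations at the first wavelength).

GLCM/GLRLM operate on the window quantized to ``levels`` equal-width bins
over the FOV intensity range.  Feature tables are pandas DataFrames with
columns ``image_id, row, col, <35 features>[, label]`` (label +1 vessel,
-1 background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi

__all__ = [
    "GlcmParams",
    "Glrlm",
    "GaborParams",
    "INTENSITY_FEATURES",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "GABOR_FEATURE_NAMES",
    "FEATURE_NAMES",
    "TABLE_RANKING",
    "intensity_moments",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "compute_glrlm",
    "glrlm_features",
    "gabor_kernel",
    "gabor_features",
    "extract_pixel_features",
]


@dataclass(frozen=True)
class GlcmParams:
    """Co-occurrence parameters: pixel distance d (default 1) and number of
    gray levels Ng (default 8; a 3x3 window has 9 pixels, so 8 levels keep
    the table populated).  Angles are fixed at 0/45/90/135 degrees and
    pooled into a single symmetric table."""

    distance: int = 1
    levels: int = 8

    def __post_init__(self):
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass(frozen=True)
class Glrlm:
    """Run-length table pooled over four directions.

    counts[i, j-1] is the number of maximal runs of gray level i (0-based)
    and length j; n_runs is the total run count and n_pixels the number of
    pixels in the patch (counted once, not per direction)."""

    counts: np.ndarray
    n_runs: int
    n_pixels: int


@dataclass(frozen=True)
class GaborParams:
    """Gabor bank: wavelengths (pixels, each > 2), orientation count over
    [0, pi), phases combined in quadrature, aspect ratio gamma and octave
    bandwidth b (which fixes the Gaussian sigma)."""

    wavelengths: tuple = (4.0, 8.0)
    n_orientations: int = 8
    aspect: float = 0.5
    bandwidth: float = 1.0

    def __post_init__(self):
        if any(lam <= 2 for lam in self.wavelengths):
            raise ValueError("each wavelength must exceed 2 pixels")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if self.aspect <= 0:
            raise ValueError("aspect ratio must be positive")


INTENSITY_FEATURES = ("mean", "variance", "skewness", "kurtosis")

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "energy",
    "entropy",
    "correlation_i",
    "correlation_ii",
    "contrast",
    "cluster_shade",
    "cluster_prominence",
    "homogeneity_i",
    "homogeneity_ii",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "maximum_probability",
    "sum_average",
    "sum_variance",
    "dissimilarity",
    "sum_of_squares_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "information_measure_correlation_i",
    "information_measure_correlation_ii",
)

GLRLM_FEATURE_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_percentage",
    "run_length_nonuniformity",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
)

GABOR_FEATURE_NAMES = ("gabor_energy", "gabor_mean_amplitude")

FEATURE_NAMES = (
    INTENSITY_FEATURES + GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES + GABOR_FEATURE_NAMES
)

# Shipped incremental-combination ordering of all 35 features (best-first).
# The source ordering lists difference_entropy twice and omits
# difference_variance; the duplicate slot (rank 33) carries
# difference_variance so that all 35 registry names appear exactly once.
TABLE_RANKING = (
    "mean",
    "cluster_prominence",
    "run_length_nonuniformity",
    "gabor_mean_amplitude",
    "low_gray_level_run_emphasis",
    "difference_entropy",
    "variance",
    "sum_of_squares_variance",
    "correlation_ii",
    "gray_level_nonuniformity",
    "gabor_energy",
    "contrast",
    "energy",
    "cluster_shade",
    "homogeneity_ii",
    "kurtosis",
    "sum_variance",
    "sum_entropy",
    "information_measure_correlation_i",
    "inverse_difference_normalized",
    "skewness",
    "information_measure_correlation_ii",
    "correlation_i",
    "high_gray_level_run_emphasis",
    "maximum_probability",
    "sum_average",
    "inverse_difference_moment_normalized",
    "homogeneity_i",
    "long_run_emphasis",
    "entropy",
    "autocorrelation",
    "dissimilarity",
    "difference_variance",
    "short_run_emphasis",
    "run_percentage",
)

assert sorted(TABLE_RANKING) == sorted(FEATURE_NAMES)


def intensity_moments(window: np.ndarray) -> dict:
    """Raw central moments of order 1-4 over the patch (divided by the pixel
    count, not standardized)."""
    w = np.asarray(window, float)
    n = w.size
    mean = w.sum() / n
    d = w - mean
    return {
        "mean": mean,
        "variance": (d**2).sum() / n,
        "skewness": (d**3).sum() / n,
        "kurtosis": (d**4).sum() / n,
    }


def quantize(img: np.ndarray, levels: int, fov: np.ndarray | None = None) -> np.ndarray:
    """Equal-width quantization to ``levels`` bins over the (FOV) range."""
    img = np.asarray(img, float)
    region = img[fov] if fov is not None else img
    lo, hi = float(region.min()), float(region.max())
    if hi - lo < 1e-12:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


_GLCM_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees


def compute_glcm(window: np.ndarray, p: GlcmParams = GlcmParams()) -> np.ndarray:
    """Normalized co-occurrence table pooled over the four angles.

    Pairs at displacement ``distance`` along each angle are counted
    symmetrically (both orders), then the table is normalized by the total
    count.  A window too small to contain any pair yields an all-zero
    (degenerate) table; its features are defined as 0.
    """
    w = np.asarray(window)
    if w.min() < 0 or w.max() > p.levels - 1:
        raise ValueError("window values must lie in [0, levels-1]")
    d = p.distance
    table = np.zeros((p.levels, p.levels))
    h, ww = w.shape
    for dy, dx in _GLCM_OFFSETS:
        oy, ox = dy * d, dx * d
        r0, r1 = max(0, -oy), min(h, h - oy)
        c0, c1 = max(0, -ox), min(ww, ww - ox)
        if r0 >= r1 or c0 >= c1:
            continue
        a = w[r0:r1, c0:c1].ravel()
        b = w[r0 + oy : r1 + oy, c0 + ox : c1 + ox].ravel()
        np.add.at(table, (a, b), 1.0)
        np.add.at(table, (b, a), 1.0)
    total = table.sum()
    return table / total if total > 0 else table


def _xlogx(v: np.ndarray) -> np.ndarray:
    """v * ln v with the 0 * log 0 := 0 convention."""
    v = np.asarray(v, float)
    out = np.zeros_like(v)
    np.log(v, out=out, where=v > 0)
    return v * out


@lru_cache(maxsize=8)
def _glcm_grids(levels: int):
    i = np.arange(1, levels + 1, dtype=float)
    gi, gj = np.meshgrid(i, i, indexing="ij")
    for g in (gi, gj):
        g.setflags(write=False)
    return gi, gj


def glcm_features(p: np.ndarray) -> dict:
    """The 22 Haralick-family statistics of a normalized GLCM.

    Logs are natural with 0*log0 := 0; gray-level indices are 1-based.
    Degenerate (all-zero) tables and zero-variance marginals map to 0 by
    guard rather than raising.
    """
    p = np.asarray(p, float)
    levels = p.shape[0]
    out = dict.fromkeys(GLCM_FEATURE_NAMES, 0.0)
    if p.sum() <= 0:
        return out
    gi, gj = _glcm_grids(levels)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    i1 = np.arange(1, levels + 1, dtype=float)
    mu_x = float((gi * p).sum())
    mu_y = float((gj * p).sum())
    var_x = float(((gi - mu_x) ** 2 * p).sum())
    var_y = float(((gj - mu_y) ** 2 * p).sum())
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)

    k_sum = np.arange(2, 2 * levels + 1, dtype=float)
    p_sum = np.bincount(
        (gi + gj).astype(int).ravel(), weights=p.ravel(), minlength=2 * levels + 1
    )[2:]
    k_diff = np.arange(0, levels, dtype=float)
    p_diff = np.bincount(
        np.abs(gi - gj).astype(int).ravel(), weights=p.ravel(), minlength=levels
    )[:levels]

    hx = -float(_xlogx(px).sum())
    hy = -float(_xlogx(py).sum())
    hxy = -float(_xlogx(p).sum())
    pxpy = np.outer(px, py)
    log_pxpy = np.zeros_like(pxpy)
    np.log(pxpy, out=log_pxpy, where=pxpy > 0)
    hxy1 = -float((p * log_pxpy).sum())
    hxy2 = -float(_xlogx(pxpy).sum())

    out["autocorrelation"] = float((gi * gj * p).sum())
    out["energy"] = float((p * p).sum())
    out["entropy"] = hxy
    if sd_x > 0 and sd_y > 0:
        out["correlation_i"] = float(
            (((gi - mu_x) * (gj - mu_y) * p).sum()) / (sd_x * sd_y)
        )
        out["correlation_ii"] = float(
            ((gi * gj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
        )
    out["contrast"] = float(((gi - gj) ** 2 * p).sum())
    out["cluster_shade"] = float(((gi + gj - mu_x - mu_y) ** 3 * p).sum())
    out["cluster_prominence"] = float(((gi + gj - mu_x - mu_y) ** 4 * p).sum())
    out["homogeneity_i"] = float((p / (1.0 + np.abs(gi - gj))).sum())
    out["homogeneity_ii"] = float((p / (1.0 + (gi - gj) ** 2)).sum())
    out["inverse_difference_normalized"] = float(
        (p / (1.0 + np.abs(gi - gj) / levels)).sum()
    )
    out["inverse_difference_moment_normalized"] = float(
        (p / (1.0 + (gi - gj) ** 2 / levels**2)).sum()
    )
    out["maximum_probability"] = float(p.max())
    out["sum_average"] = float((k_sum * p_sum).sum())
    sum_entropy = -float(_xlogx(p_sum).sum())
    out["sum_entropy"] = sum_entropy
    # as printed: Sum Entropy (signed as sum of p log p) sits inside the square
    out["sum_variance"] = float(((k_sum - sum_entropy) ** 2 * p_sum).sum())
    out["dissimilarity"] = float((np.abs(gi - gj) * p).sum())
    out["sum_of_squares_variance"] = float(((gi - mu_x) ** 2 * p).sum())
    out["difference_variance"] = float((k_diff**2 * p_diff).sum())
    out["difference_entropy"] = -float(_xlogx(p_diff).sum())
    hmax = max(hx, hy)
    if hmax > 0:
        out["information_measure_correlation_i"] = (hxy - hxy1) / hmax
    out["information_measure_correlation_ii"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    return out


def _run_lengths(seq: np.ndarray):
    """Maximal constant runs of a 1-D sequence as (value, length) pairs."""
    runs = []
    start = 0
    for k in range(1, len(seq) + 1):
        if k == len(seq) or seq[k] != seq[start]:
            runs.append((int(seq[start]), k - start))
            start = k
    return runs


def _direction_lines(w: np.ndarray):
    """The scan lines of a patch along 0, 45, 90 and 135 degrees."""
    h, ww = w.shape
    lines = [w[r, :] for r in range(h)]                      # 0 deg
    lines += [w[:, c] for c in range(ww)]                    # 90 deg
    flipped = w[:, ::-1]
    for off in range(-(h - 1), ww):                          # 45 / 135 deg
        lines.append(np.diagonal(flipped, offset=off))
        lines.append(np.diagonal(w, offset=off))
    return lines


def compute_glrlm(window: np.ndarray, levels: int = 8) -> Glrlm:
    """Run-length table pooled over the four directions.

    Each maximal collinear constant-level run contributes one count at
    (level, length).  ``n_pixels`` is the patch pixel count (counted once).
    """
    w = np.asarray(window)
    if w.min() < 0 or w.max() > levels - 1:
        raise ValueError("window values must lie in [0, levels-1]")
    max_len = max(w.shape)
    counts = np.zeros((levels, max_len))
    n_runs = 0
    for line in _direction_lines(w):
        for value, length in _run_lengths(np.asarray(line)):
            counts[value, length - 1] += 1
            n_runs += 1
    return Glrlm(counts=counts, n_runs=n_runs, n_pixels=w.size)


def glrlm_features(r: Glrlm) -> dict:
    """The seven run-length statistics.

    Gray-level indices i are counted from 1 in the i^2 terms; run length j
    is 1-based.  ``n_runs = 0`` maps every feature to 0.
    """
    out = dict.fromkeys(GLRLM_FEATURE_NAMES, 0.0)
    if r.n_runs <= 0:
        return out
    counts = np.asarray(r.counts, float)
    levels, max_len = counts.shape
    i = np.arange(1, levels + 1, dtype=float)
    j = np.arange(1, max_len + 1, dtype=float)
    p_g = counts.sum(axis=1)
    p_r = counts.sum(axis=0)
    nr = float(r.n_runs)
    out["short_run_emphasis"] = float((p_r / j**2).sum()) / nr
    out["long_run_emphasis"] = float((p_r * j**2).sum()) / nr
    out["gray_level_nonuniformity"] = float((p_g**2).sum()) / nr
    out["run_percentage"] = nr / float(r.n_pixels)
    out["run_length_nonuniformity"] = float((p_r**2).sum()) / nr
    out["low_gray_level_run_emphasis"] = float((p_g / i**2).sum()) / nr
    out["high_gray_level_run_emphasis"] = float((p_g * i**2).sum()) / nr
    return out


def _gabor_sigma(wavelength: float, bandwidth: float) -> float:
    """Gaussian sigma from the octave bandwidth b (standard relation)."""
    factor = (2.0**bandwidth + 1.0) / (2.0**bandwidth - 1.0)
    return wavelength / np.pi * np.sqrt(np.log(2.0) / 2.0) * factor


def gabor_kernel(
    wavelength: float,
    theta: float,
    phase: float = 0.0,
    aspect: float = 0.5,
    bandwidth: float = 1.0,
) -> np.ndarray:
    """Gaussian-modulated sinusoid selective for stripes orthogonal to theta.

    ``K(x, y) = exp(-(x'^2 + gamma^2 y'^2)/(2 sigma^2)) cos(2 pi x'/lambda
    + phase)`` with (x', y') the coordinates rotated by theta and sigma set
    from the octave bandwidth.  phase 0 gives an even (symmetric) kernel.
    """
    if wavelength <= 2:
        raise ValueError("wavelength must exceed 2 pixels")
    sigma = _gabor_sigma(wavelength, bandwidth)
    r = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    return np.exp(-(xp**2 + aspect**2 * yp**2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * xp / wavelength + phase
    )


def _local_abs_dev_energy(resp: np.ndarray, window: int) -> np.ndarray:
    """Local squared energy: (mean_W |R - mu_W|)^2 with mu_W the window mean
    at the center pixel; edge-replicated."""
    r = window // 2
    padded = np.pad(resp, r, mode="edge")
    win = sliding_window_view(padded, (window, window))
    mu = win.mean(axis=(-2, -1))
    return np.abs(win - mu[..., None, None]).mean(axis=(-2, -1)) ** 2


def gabor_features(
    img: np.ndarray, p: GaborParams = GaborParams(), window: int = 3
) -> dict:
    """Per-wavelength Gabor feature maps.

    For each wavelength, the image is convolved with the oriented bank
    (reflect boundary); the amplitude map is the quadrature magnitude
    (phases 0 and pi/2) averaged over orientations, and the energy map is
    the window-local squared energy of the even response averaged over
    orientations.  Returns ``{wavelength: {"energy": map, "amplitude": map}}``.
    """
    img = np.asarray(img, float)
    thetas = [k * np.pi / p.n_orientations for k in range(p.n_orientations)]
    out = {}
    for lam in p.wavelengths:
        amp_acc = np.zeros_like(img)
        energy_acc = np.zeros_like(img)
        for theta in thetas:
            even = ndi.convolve(
                img, gabor_kernel(lam, theta, 0.0, p.aspect, p.bandwidth),
                mode="reflect",
            )
            odd = ndi.convolve(
                img, gabor_kernel(lam, theta, np.pi / 2, p.aspect, p.bandwidth),
                mode="reflect",
            )
            amp_acc += np.sqrt(even**2 + odd**2)
            energy_acc += _local_abs_dev_energy(even, window)
        out[lam] = {
            "energy": energy_acc / p.n_orientations,
            "amplitude": amp_acc / p.n_orientations,
        }
    return out


def extract_pixel_features(
    img: np.ndarray,
    fov: np.ndarray,
    window: int = 3,
    glcm_params: GlcmParams = GlcmParams(),
    gabor_params: GaborParams = GaborParams(),
    pixels: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    image_id: str = "img",
) -> pd.DataFrame:
    """Feature table for the requested FOV pixels (default: every FOV pixel).

    ``pixels`` is an (N, 2) array of (row, col); pixels outside the FOV are
    skipped with a warning.  ``labels`` is an optional truth mask from which
    a +1/-1 label column is read.  Windows at the image border are
    edge-replicated; quantization spans the FOV intensity range; Gabor maps
    are computed once on the full image and sampled at each pixel.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    img = np.asarray(img, float)
    fov = np.asarray(fov, bool)
    if pixels is None:
        pixels = np.argwhere(fov)
    else:
        pixels = np.asarray(pixels, int)
        inside = fov[pixels[:, 0], pixels[:, 1]]
        if not inside.all():
            warnings.warn(
                f"{int((~inside).sum())} requested pixel(s) outside the FOV "
                "were skipped",
                stacklevel=2,
            )
            pixels = pixels[inside]

    quantized = quantize(img, glcm_params.levels, fov)
    r = window // 2
    img_pad = np.pad(img, r, mode="edge")
    q_pad = np.pad(quantized, r, mode="edge")
    gabor_maps = gabor_features(img, gabor_params, window)
    first = gabor_maps[gabor_params.wavelengths[0]]

    records = np.empty((len(pixels), len(FEATURE_NAMES)))
    for n, (row, col) in enumerate(pixels):
        wi = img_pad[row : row + window, col : col + window]
        wq = q_pad[row : row + window, col : col + window]
        feats = intensity_moments(wi)
        feats.update(glcm_features(compute_glcm(wq, glcm_params)))
        feats.update(glrlm_features(compute_glrlm(wq, glcm_params.levels)))
        feats["gabor_energy"] = first["energy"][row, col]
        feats["gabor_mean_amplitude"] = first["amplitude"][row, col]
        records[n] = [feats[name] for name in FEATURE_NAMES]

    table = pd.DataFrame(records, columns=list(FEATURE_NAMES))
    table.insert(0, "col", pixels[:, 1] if len(pixels) else np.array([], int))
    table.insert(0, "row", pixels[:, 0] if len(pixels) else np.array([], int))
    table.insert(0, "image_id", image_id)
    if labels is not None:
        truth = np.asarray(labels, bool)
        table["label"] = np.where(
            truth[pixels[:, 0], pixels[:, 1]], 1, -1
        ) if len(pixels) else np.array([], int)
    return table
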