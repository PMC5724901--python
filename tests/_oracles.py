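"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration, nested
loops or closed form, deliberately avoiding the code paths of the package
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def median_filter_oracle(img: np.ndarray, size: int) -> np.ndarray:
    """Median by explicit neighborhood sort, edge-replicated."""
    r = size // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(np.asarray(img, float))
    for row in range(img.shape[0]):
        for col in range(img.shape[1]):
            window = padded[row : row + size, col : col + size].ravel()
            out[row, col] = np.sort(window)[window.size // 2]
    return out


def erode_oracle(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale erosion by sliding-window min over the footprint, reflect."""
    r = footprint.shape[0] // 2
    padded = np.pad(img, r, mode="reflect")
    out = np.empty_like(np.asarray(img, float))
    offs = np.argwhere(footprint) - r
    for row in range(img.shape[0]):
        for col in range(img.shape[1]):
            out[row, col] = min(
                padded[row + r + dy, col + r + dx] for dy, dx in offs
            )
    return out


def dilate_oracle(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    r = footprint.shape[0] // 2
    padded = np.pad(img, r, mode="reflect")
    out = np.empty_like(np.asarray(img, float))
    offs = np.argwhere(footprint) - r
    for row in range(img.shape[0]):
        for col in range(img.shape[1]):
            out[row, col] = max(
                padded[row + r + dy, col + r + dx] for dy, dx in offs
            )
    return out


def opening_oracle(img, footprint):
    return dilate_oracle(erode_oracle(img, footprint), footprint)


def closing_oracle(img, footprint):
    return erode_oracle(dilate_oracle(img, footprint), footprint)


def bilateral_oracle(img: np.ndarray, window: int, sigma_d: float, sigma_r: float):
    """Direct double-loop evaluation of the windowed bilateral filter."""
    r = window // 2
    padded = np.pad(img, r, mode="reflect")
    out = np.empty_like(np.asarray(img, float))
    for row in range(img.shape[0]):
        for col in range(img.shape[1]):
            num = den = 0.0
            center = img[row, col]
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    val = padded[row + r + dy, col + r + dx]
                    g = np.exp(-0.5 * (dy * dy + dx * dx) / sigma_d**2)
                    s = np.exp(-0.5 * ((val - center) / sigma_r) ** 2)
                    num += val * g * s
                    den += g * s
            out[row, col] = num / den
    return out


def smooth_border_oracle(img: np.ndarray, mask: np.ndarray, iterations: int):
    """Per-pixel simulation of the iterative FOV rim fill."""
    img = np.asarray(img, float).copy()
    mask = np.asarray(mask, bool).copy()
    h, w = img.shape
    for _ in range(iterations):
        new_vals = {}
        for row in range(h):
            for col in range(w):
                if mask[row, col]:
                    continue
                inside = [
                    img[row + dy, col + dx]
                    for dy in (-1, 0, 1)
                    for dx in (-1, 0, 1)
                    if (dy or dx)
                    and 0 <= row + dy < h
                    and 0 <= col + dx < w
                    and mask[row + dy, col + dx]
                ]
                if inside:
                    new_vals[(row, col)] = float(np.mean(inside))
        for (row, col), val in new_vals.items():
            img[row, col] = val
            mask[row, col] = True
    return img, mask


def convolve_oracle(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop 2-D correlation-style convolution, reflect-padded,
    matching scipy.ndimage.convolve's flipped-kernel convention."""
    r = kernel.shape[0] // 2
    flipped = kernel[::-1, ::-1]
    padded = np.pad(img, r, mode="reflect")
    out = np.empty_like(np.asarray(img, float))
    for row in range(img.shape[0]):
        for col in range(img.shape[1]):
            window = padded[row : row + kernel.shape[0], col : col + kernel.shape[1]]
            out[row, col] = float((window * flipped).sum())
    return out


def bcosfire_oracle(img: np.ndarray, cfg) -> np.ndarray:
    """Direct evaluation of the B-COSFIRE response.

    Rebuilds the DoG kernel, convolves by nested loops, blurs each point by
    an explicit max over the Gaussian-weighted square support, shifts by
    reading displaced coordinates (zero outside the frame), and combines by
    an explicitly-computed weighted geometric mean.
    """
    from retinaseg.matched_filters import dog_kernel

    c = np.maximum(convolve_oracle(img, dog_kernel(cfg.sigma)), 0.0)
    h, w = img.shape
    rhos = np.array([pt.rho for pt in cfg.points])
    rho_max = rhos.max()
    if rho_max == 0:
        weights = np.ones(len(rhos))
    else:
        sigma_hat = rho_max / 3.0
        weights = np.exp(-(rhos**2) / (2 * sigma_hat**2))

    shifted_maps = []
    for pt in cfg.points:
        sp = cfg.sigma0 + cfg.alpha * pt.rho
        radius = max(1, int(np.floor(3.0 * sp)))
        gauss = np.empty((2 * radius + 1, 2 * radius + 1))
        for yy in range(-radius, radius + 1):
            for xx in range(-radius, radius + 1):
                gauss[yy + radius, xx + radius] = np.exp(
                    -(xx * xx + yy * yy) / (2 * sp * sp)
                ) / (2 * np.pi * sp * sp)
        cpad = np.pad(c, radius, mode="reflect")
        blurred = np.empty_like(c)
        for row in range(h):
            for col in range(w):
                window = cpad[row : row + 2 * radius + 1, col : col + 2 * radius + 1]
                blurred[row, col] = float((window * gauss).max())
        dx = int(np.round(-pt.rho * np.cos(pt.phi)))
        dy = int(np.round(-pt.rho * np.sin(pt.phi)))
        shifted = np.zeros_like(blurred)
        for row in range(h):
            for col in range(w):
                sr, sc = row - dy, col - dx
                if 0 <= sr < h and 0 <= sc < w:
                    shifted[row, col] = blurred[sr, sc]
        shifted_maps.append(shifted)

    out = np.empty((h, w))
    wsum = weights.sum()
    for row in range(h):
        for col in range(w):
            vals = [m[row, col] for m in shifted_maps]
            if any(v == 0.0 for v in vals):
                out[row, col] = 0.0
            else:
                prod = 1.0
                for v, omega in zip(vals, weights):
                    prod *= v**omega
                out[row, col] = prod ** (1.0 / wsum)
    if cfg.t > 0:
        out[out < cfg.t * out.max()] = 0.0
    return out


def glcm_oracle(window: np.ndarray, distance: int, levels: int) -> np.ndarray:
    """Exhaustive pair enumeration: every ordered pixel pair whose
    displacement matches one of the four angles at the given distance."""
    w = np.asarray(window)
    h, ww = w.shape
    table = np.zeros((levels, levels))
    displacements = {
        (0, distance), (0, -distance),
        (distance, 0), (-distance, 0),
        (distance, distance), (-distance, -distance),
        (distance, -distance), (-distance, distance),
    }
    for (r1, c1), (r2, c2) in itertools.product(
        itertools.product(range(h), range(ww)), repeat=2
    ):
        if (r2 - r1, c2 - c1) in displacements:
            table[w[r1, c1], w[r2, c2]] += 1
    total = table.sum()
    return table / total if total else table


def glrlm_oracle(window: np.ndarray, levels: int):
    """Run enumeration with itertools.groupby over explicitly-built
    coordinate lines in the four directions."""
    w = np.asarray(window)
    h, ww = w.shape
    counts = np.zeros((levels, max(h, ww)))
    lines = []
    for row in range(h):
        lines.append([(row, col) for col in range(ww)])
    for col in range(ww):
        lines.append([(row, col) for row in range(h)])
    for s in range(h + ww - 1):  # anti-diagonals (45 deg)
        lines.append(
            [(row, s - row) for row in range(h) if 0 <= s - row < ww]
        )
    for d in range(-(h - 1), ww):  # diagonals (135 deg)
        lines.append(
            [(row, row + d) for row in range(h) if 0 <= row + d < ww]
        )
    n_runs = 0
    for line in lines:
        values = [int(w[r, c]) for r, c in line]
        for value, group in itertools.groupby(values):
            counts[value, len(list(group)) - 1] += 1
            n_runs += 1
    return counts, n_runs


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized count of concordant positive/negative pairs
    (ties count one half)."""
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
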