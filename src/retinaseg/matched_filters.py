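"""Matched-filter vessel enhancement: DoG fields, symmetric/asymmetric
B-COSFIRE with rotation invariance, and multi-scale Frangi vesselness.

The DoG kernel used here is ``G_sigma - G_{0.5 sigma}`` (both Gaussians
unit-normalized), which is negative at the origin and therefore responds to
*dark* bars on a brighter background.  The pipeline feeds these filters the
complement of the bright-vessel enhanced image, which is algebraically the
same as running a positive-center DoG on the bright-vessel image itself
(the DoG of a constant is zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "CosfirePoint",
    "CosfireConfig",
    "FrangiParams",
    "dog_kernel",
    "dog_response",
    "make_line_config",
    "default_symmetric_config",
    "default_asymmetric_config",
    "bcosfire_response",
    "rotation_invariant_response",
    "combined_bcosfire",
    "frangi_vesselness",
]

_ZERO_FLOOR = 1e-200  # responses below this are true zeros of the AND combination


@dataclass(frozen=True)
class CosfirePoint:
    """One DoG-response position in polar coordinates (radius rho in pixels,
    angle phi in radians, measured from the +x / column axis)."""

    rho: float
    phi: float


@dataclass(frozen=True)
class CosfireConfig:
    """A B-COSFIRE filter: the point set S plus its tolerance parameters.

    sigma  : standard deviation of the underlying DoG.
    sigma0 : base of the position-tolerance blur, sigma' = sigma0 + alpha*rho.
    alpha  : slope of the position-tolerance blur.
    t      : response threshold as a fraction of the maximum (0 disables).
    n_orientations : orientations used for rotation invariance
                     (theta_k = k*pi/n, k = 0..n-1; default 12).
    """

    points: tuple
    sigma: float
    sigma0: float
    alpha: float
    t: float = 0.0
    n_orientations: int = 12
    symmetric: bool = True

    def __post_init__(self):
        if len(self.points) == 0:
            raise ValueError("point set S must be non-empty")
        if not (0.0 <= self.t <= 1.0):
            raise ValueError("threshold fraction t must be in [0, 1]")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")
        if self.sigma <= 0 or self.sigma0 <= 0:
            raise ValueError("sigma and sigma0 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass(frozen=True)
class FrangiParams:
    """Frangi vesselness parameters.

    alpha : blob discrimination scale (on R_b = |l1|/|l2|), default 0.9.
    beta  : structureness scale (on S = sqrt(l1^2 + l2^2)), default 13.
    sigmas: increasing Gaussian-derivative scales, default 1, 1.1, ..., 4.
    """

    alpha: float = 0.9
    beta: float = 13.0
    sigmas: tuple = tuple(np.round(np.arange(1.0, 4.0 + 1e-9, 0.1), 1))

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        s = np.asarray(self.sigmas, float)
        if s.size == 0 or (np.diff(s) <= 0).any():
            raise ValueError("sigmas must be a non-empty increasing sequence")


def dog_kernel(sigma: float) -> np.ndarray:
    """Difference-of-Gaussians kernel: G_sigma - G_{0.5 sigma}.

    Each Gaussian is unit-normalized analytically (1/(2 pi s^2) peak factor),
    so the kernel integrates to ~0 and its origin value is -3/(2 pi sigma^2).
    Support radius is ceil(4 sigma).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = int(np.ceil(4.0 * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    d2 = x * x + y * y

    def g(s):
        return np.exp(-d2 / (2.0 * s * s)) / (2.0 * np.pi * s * s)

    return g(sigma) - g(0.5 * sigma)


def dog_response(img: np.ndarray, sigma: float) -> np.ndarray:
    """Half-wave rectified DoG response (reflect boundary)."""
    kernel = dog_kernel(sigma)
    resp = ndi.convolve(np.asarray(img, float), kernel, mode="reflect")
    return np.maximum(resp, 0.0)


def make_line_config(
    rho_list,
    orientation: float = np.pi / 2,
    symmetric: bool = True,
    sigma: float = 2.4,
    sigma0: float = 3.0,
    alpha: float = 0.6,
    t: float = 0.0,
    n_orientations: int = 12,
) -> CosfireConfig:
    """Analytic line-detector configuration.

    For a symmetric (bar) filter each radius rho > 0 contributes two points,
    at ``orientation`` and ``orientation + pi``, plus the center (0, 0); an
    asymmetric (bar-ending) filter keeps only one side.
    """
    rho_list = sorted({float(r) for r in rho_list})
    if not rho_list:
        raise ValueError("rho_list must be non-empty")
    if rho_list[0] < 0:
        raise ValueError("radii must be non-negative")
    points = []
    if rho_list[0] == 0.0:
        points.append(CosfirePoint(0.0, 0.0))
        rho_list = rho_list[1:]
    for rho in rho_list:
        points.append(CosfirePoint(rho, orientation % (2 * np.pi)))
        if symmetric:
            points.append(CosfirePoint(rho, (orientation + np.pi) % (2 * np.pi)))
    return CosfireConfig(
        points=tuple(points),
        sigma=sigma,
        sigma0=sigma0,
        alpha=alpha,
        t=t,
        n_orientations=n_orientations,
        symmetric=symmetric,
    )


def default_symmetric_config(t: float = 0.0, n_orientations: int = 12) -> CosfireConfig:
    """Bar detector: sigma 2.4, rho {0, 2, ..., 10}, sigma0 3, alpha 0.6."""
    return make_line_config(
        range(0, 12, 2), symmetric=True, sigma=2.4, sigma0=3.0, alpha=0.6,
        t=t, n_orientations=n_orientations,
    )


def default_asymmetric_config(t: float = 0.0, n_orientations: int = 12) -> CosfireConfig:
    """Bar-ending detector: sigma 2.1, rho {0, 2, ..., 18}, sigma0 1, alpha 0.1."""
    return make_line_config(
        range(0, 20, 2), symmetric=False, sigma=2.1, sigma0=1.0, alpha=0.1,
        t=t, n_orientations=n_orientations,
    )


def _blur_max(resp: np.ndarray, sigma_prime: float) -> np.ndarray:
    """Position-tolerance blur: max over the support of resp * G_sigma'.

    ``G`` is the normalized Gaussian and the support is the square
    |x'|, |y'| <= 3 sigma'.  Computed exactly in the log domain with a
    grayscale dilation (max-plus convolution).
    """
    r = max(1, int(np.floor(3.0 * sigma_prime)))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    g = np.exp(-(x * x + y * y) / (2.0 * sigma_prime**2)) / (
        2.0 * np.pi * sigma_prime**2
    )
    log_resp = np.log(np.maximum(resp, 1e-300))
    out = ndi.grey_dilation(log_resp, structure=np.log(g), mode="reflect")
    return np.exp(out)


def _shift_int(arr: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer shift with zero fill: out[r, c] = arr[r - dy, c - dx]."""
    out = np.zeros_like(arr)
    h, w = arr.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_r = slice(max(0, dy), min(h, h + dy))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def _weights(rhos: np.ndarray) -> np.ndarray:
    """Point weights omega_i = exp(-rho_i^2 / (2 sigma_hat^2)),
    sigma_hat = max(rho)/3; all ones when the set has a single center point."""
    rho_max = float(rhos.max())
    if rho_max == 0.0:
        return np.ones_like(rhos)
    sigma_hat = rho_max / 3.0
    return np.exp(-(rhos**2) / (2.0 * sigma_hat**2))


def _geometric_mean(shifted: list, weights: np.ndarray) -> np.ndarray:
    """Weighted geometric mean with AND semantics: zero wherever any
    contributing response is zero."""
    stack = np.stack(shifted)
    zero = (stack <= _ZERO_FLOOR).any(axis=0)
    logs = np.log(np.maximum(stack, _ZERO_FLOOR))
    out = np.exp(np.tensordot(weights, logs, axes=1) / weights.sum())
    out[zero] = 0.0
    return out


def _apply_threshold(resp: np.ndarray, t: float) -> np.ndarray:
    if t > 0:
        resp = resp.copy()
        resp[resp < t * resp.max()] = 0.0
    return resp


def _response_for_points(blurred: dict, points, weights: np.ndarray) -> np.ndarray:
    shifted = []
    for pt in points:
        dx = int(np.round(-pt.rho * np.cos(pt.phi)))
        dy = int(np.round(-pt.rho * np.sin(pt.phi)))
        shifted.append(_shift_int(blurred[pt.rho], dy, dx))
    return _geometric_mean(shifted, weights)


def _blur_cache(img: np.ndarray, cfg: CosfireConfig) -> dict:
    c = dog_response(img, cfg.sigma)
    return {
        rho: _blur_max(c, cfg.sigma0 + cfg.alpha * rho)
        for rho in sorted({pt.rho for pt in cfg.points})
    }


def bcosfire_response(img: np.ndarray, cfg: CosfireConfig) -> np.ndarray:
    """Single-orientation B-COSFIRE response.

    Each DoG-response position is blurred (Gaussian-weighted max with
    sigma' = sigma0 + alpha*rho), shifted back to the filter center, and the
    shifted responses are combined by their weighted geometric mean -- an
    AND-type combination that responds only where every point responds.
    The result is thresholded at fraction ``t`` of its maximum.
    """
    blurred = _blur_cache(img, cfg)
    rhos = np.array([pt.rho for pt in cfg.points], float)
    resp = _response_for_points(blurred, cfg.points, _weights(rhos))
    return _apply_threshold(resp, cfg.t)


def rotation_invariant_response(img: np.ndarray, cfg: CosfireConfig) -> np.ndarray:
    """Pixelwise max over n_orientations rotated copies of the point set.

    Orientation k uses the point set {(rho_i, phi_i + k*pi/n)}; the blurred
    DoG responses are orientation-independent and computed once.
    """
    blurred = _blur_cache(img, cfg)
    rhos = np.array([pt.rho for pt in cfg.points], float)
    weights = _weights(rhos)
    out = None
    for k in range(cfg.n_orientations):
        theta = k * np.pi / cfg.n_orientations
        pts = [CosfirePoint(pt.rho, pt.phi + theta) for pt in cfg.points]
        resp = _response_for_points(blurred, pts, weights)
        out = resp if out is None else np.maximum(out, resp)
    return _apply_threshold(out, cfg.t)


def combined_bcosfire(
    img: np.ndarray,
    sym: CosfireConfig | None = None,
    asym: CosfireConfig | None = None,
) -> np.ndarray:
    """Sum of the rotation-invariant symmetric and asymmetric responses.

    The symmetric filter responds along vessels, the asymmetric one at
    vessel endings; their sum covers both.  Defaults are the bar/bar-ending
    configurations of :func:`default_symmetric_config` and
    :func:`default_asymmetric_config`.
    """
    sym = sym if sym is not None else default_symmetric_config()
    asym = asym if asym is not None else default_asymmetric_config()
    return rotation_invariant_response(img, sym) + rotation_invariant_response(
        img, asym
    )


def frangi_vesselness(img: np.ndarray, p: FrangiParams = FrangiParams()) -> np.ndarray:
    """Multi-scale Hessian vesselness for bright tubular structures.

    Per scale sigma the Hessian is built from sigma-scaled Gaussian
    derivatives (sigma^2-normalized); with eigenvalues ordered
    |l1| <= |l2| the response is 0 where l2 > 0 (bright ridges have
    l2 < 0) and otherwise
    ``exp(-R_b^2/(2 alpha^2)) * (1 - exp(-S^2/(2 beta^2)))`` with
    R_b = |l1|/|l2| and S = sqrt(l1^2 + l2^2).  The final map is the
    pixelwise max over scales; values lie in [0, 1).
    """
    img = np.asarray(img, float)
    out = np.zeros_like(img)
    for sigma in p.sigmas:
        s2 = sigma * sigma
        hrr = ndi.gaussian_filter(img, sigma, order=(2, 0), mode="reflect") * s2
        hcc = ndi.gaussian_filter(img, sigma, order=(0, 2), mode="reflect") * s2
        hrc = ndi.gaussian_filter(img, sigma, order=(1, 1), mode="reflect") * s2
        # eigenvalues of [[hrr, hrc], [hrc, hcc]]
        tmp = np.sqrt((hrr - hcc) ** 2 + 4.0 * hrc * hrc)
        mu1 = 0.5 * (hrr + hcc + tmp)
        mu2 = 0.5 * (hrr + hcc - tmp)
        swap = np.abs(mu1) > np.abs(mu2)
        lam1 = np.where(swap, mu2, mu1)  # |lam1| <= |lam2|
        lam2 = np.where(swap, mu1, mu2)
        abs2 = np.abs(lam2)
        rb = np.divide(np.abs(lam1), abs2, out=np.zeros_like(abs2), where=abs2 > 0)
        s_struct = np.sqrt(lam1 * lam1 + lam2 * lam2)
        f = np.exp(-(rb * rb) / (2.0 * p.alpha**2)) * (
            1.0 - np.exp(-(s_struct * s_struct) / (2.0 * p.beta**2))
        )
        f[lam2 > 0] = 0.0
        np.maximum(out, f, out=out)
    return out
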