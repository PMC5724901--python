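"""Deterministic generator of fundus-like fixtures with known vessel truth.

Each fixture is a small color image emulating the properties the pipeline
targets: a dark branching vessel tree with Gaussian cross-section on a
brighter background (strongest in the green channel), smooth multiplicative
illumination inhomogeneity, additive Gaussian noise, and a circular field of
view on a black surround.  The geometry is a curvature-bounded random walk
with stochastic branching, seeded, so a fixed seed reproduces the image
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = ["SyntheticSpec", "generate_vessel_tree", "generate_images", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of a synthetic fixture.

    size                   : (H, W) in pixels, default 96x96 (a scaled-down
                             fundus frame).
    n_trees                : vessel trees rooted on the FOV rim.
    width_range            : vessel diameters in pixels, sampled per branch.
    contrast               : vessel-to-background intensity gap (fraction of
                             the background level).
    illumination_amplitude : peak relative deviation of the smooth
                             multiplicative illumination field.
    noise_sigma            : additive Gaussian noise sigma on [0, 1].
    fov_radius             : FOV radius as a fraction of min(H, W).
    """

    size: tuple = (96, 96)
    n_trees: int = 2
    width_range: tuple = (1.0, 4.0)
    contrast: float = 0.25
    illumination_amplitude: float = 0.15
    noise_sigma: float = 0.02
    fov_radius: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if min(self.width_range) < 1:
            raise ValueError("vessel widths must be >= 1 px")
        if not (0 <= self.illumination_amplitude < 1):
            raise ValueError("illumination amplitude must be in [0, 1)")
        if not (0 <= self.contrast < 1):
            raise ValueError("contrast must be in [0, 1)")


_BACKGROUND_GREEN = 0.55
_STEP = 1.0          # centerline step length, px
_TURN_SIGMA = 0.10   # per-step direction jitter, rad
_BRANCH_PROB = 0.02  # per-step branch probability
_TAPER = 0.998       # per-step width multiplier


def _stamp(darkness, truth, pos, width, shape):
    """Render one centerline point: Gaussian profile + hard truth disk."""
    h, w = shape
    sigma = max(width / 2.5, 0.45)
    radius = int(np.ceil(max(width / 2.0, 3.0 * sigma)))
    r0 = int(np.floor(pos[0])) - radius
    c0 = int(np.floor(pos[1])) - radius
    r1, c1 = r0 + 2 * radius + 1, c0 + 2 * radius + 1
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, h), min(c1, w)
    if rr0 >= rr1 or cc0 >= cc1:
        return
    yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
    d2 = (yy - pos[0]) ** 2 + (xx - pos[1]) ** 2
    np.maximum(
        darkness[rr0:rr1, cc0:cc1],
        np.exp(-d2 / (2.0 * sigma * sigma)),
        out=darkness[rr0:rr1, cc0:cc1],
    )
    truth[rr0:rr1, cc0:cc1] |= d2 <= (width / 2.0) ** 2


def generate_vessel_tree(spec: SyntheticSpec):
    """One fixture: (RGB uint8 image, truth mask, FOV mask).

    Trees start on the FOV rim heading inward; each walker advances in unit
    steps with Gaussian direction jitter, tapers slowly, and spawns a
    narrower branch with a small per-step probability.  Walkers stop when
    they leave the FOV.  The truth mask is the union of disks of the local
    width around every centerline point, clipped to the FOV.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = spec.fov_radius * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    fov = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    darkness = np.zeros((h, w))
    truth = np.zeros((h, w), dtype=bool)
    wmin, wmax = spec.width_range
    stack = []
    for _ in range(spec.n_trees):
        ang = rng.uniform(0, 2 * np.pi)
        start = np.array([cy + 0.92 * radius * np.sin(ang),
                          cx + 0.92 * radius * np.cos(ang)])
        heading = ang + np.pi + rng.uniform(-0.4, 0.4)
        width = rng.uniform(0.5 * (wmin + wmax), wmax)
        stack.append((start, heading, width))

    max_steps = int(4 * radius)
    while stack:
        pos, heading, width = stack.pop()
        pos = pos.copy()
        for _ in range(max_steps):
            if (pos[0] - cy) ** 2 + (pos[1] - cx) ** 2 > (0.97 * radius) ** 2:
                break
            _stamp(darkness, truth, pos, width, (h, w))
            heading += rng.normal(0.0, _TURN_SIGMA)
            pos[0] += _STEP * np.sin(heading)
            pos[1] += _STEP * np.cos(heading)
            width = max(wmin, width * _TAPER)
            if width > 1.2 * wmin and rng.random() < _BRANCH_PROB:
                side = 1 if rng.random() < 0.5 else -1
                stack.append(
                    (pos.copy(), heading + side * rng.uniform(0.4, 0.9),
                     max(wmin, 0.7 * width))
                )
    truth &= fov

    illum = np.ones((h, w))
    if spec.illumination_amplitude > 0:
        field = ndi.gaussian_filter(rng.standard_normal((h, w)), min(h, w) / 4.0)
        peak = np.abs(field).max()
        if peak > 0:
            illum += spec.illumination_amplitude * field / peak
    green = _BACKGROUND_GREEN * (1.0 - spec.contrast * darkness) * illum
    if spec.noise_sigma > 0:
        green = green + rng.normal(0.0, spec.noise_sigma, (h, w))
    green = np.clip(green, 0.0, 1.0)
    red = np.clip(green * 1.3 + 0.18, 0.0, 1.0)
    blue = np.clip(green * 0.35, 0.0, 1.0)
    rgb = np.stack([red, green, blue], axis=-1)
    rgb[~fov] = 0.0
    return (np.round(rgb * 255).astype(np.uint8), truth, fov)


def generate_images(n: int, spec: SyntheticSpec):
    """``n`` fixtures with incremented sub-seeds (spec.seed + i)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_vessel_tree(replace(spec, seed=spec.seed + i)) for i in range(n)]


def generate_dataset(
    n: int, spec: SyntheticSpec, out_dir, prefix: str = "synth", role: str = "train"
) -> pd.DataFrame:
    """Write ``n`` fixtures (image/truth/FOV PNGs) plus a manifest CSV.

    The manifest has columns image, truth, fov, role and is written to
    ``out_dir/manifest.csv``; it is the on-disk form consumed by the CLI.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth, fov) in enumerate(generate_images(n, spec)):
        stem = f"{prefix}_{i:02d}"
        paths = {
            "image": out_dir / f"{stem}.png",
            "truth": out_dir / f"{stem}_truth.png",
            "fov": out_dir / f"{stem}_fov.png",
        }
        iio.imwrite(paths["image"], img)
        iio.imwrite(paths["truth"], truth.astype(np.uint8) * 255)
        iio.imwrite(paths["fov"], fov.astype(np.uint8) * 255)
        rows.append(
            {"image": str(paths["image"]), "truth": str(paths["truth"]),
             "fov": str(paths["fov"]), "role": role}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
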