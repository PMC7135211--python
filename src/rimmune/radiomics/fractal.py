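"""Fractal model-based features: box-counting dimensions and lacunarity.

Three features: (1) box-counting dimension of the mask surface,
(2) intensity fractal dimension by differential box counting inside the
mask, and (3) lacunarity of the mask occupancy at a fixed gliding-box
size.  Dimensions come from a least-squares fit of log N(eps) against
log(1/eps) over a dyadic box-size ladder; fewer than three usable
ladder points yield a missing value.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from rimmune.volume import VolumeROI

logger = logging.getLogger(__name__)

__all__ = [
    "boxcount_dimension",
    "differential_boxcount_dimension",
    "lacunarity",
    "fractal_features",
]


def _block_reduce_any(binary: np.ndarray, size: int) -> np.ndarray:
    """Occupancy of non-overlapping size^3 blocks (padded with False)."""
    pad = [(0, (-n) % size) for n in binary.shape]
    b = np.pad(binary, pad)
    nz, ny, nx = (n // size for n in b.shape)
    return b.reshape(nz, size, ny, size, nx, size).any(axis=(1, 3, 5))


def boxcount_dimension(binary: np.ndarray) -> float:
    """Box-counting dimension of a binary set over a dyadic size ladder."""
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return float("nan")
    max_size = max(2, min(binary.shape) // 2)
    sizes = []
    s = 1
    while s <= max_size:
        sizes.append(s)
        s *= 2
    counts = [int(_block_reduce_any(binary, s).sum()) for s in sizes]
    pts = [(s, c) for s, c in zip(sizes, counts) if c > 0]
    if len(pts) < 3:
        logger.info("box-count ladder has <3 usable points; dimension missing")
        return float("nan")
    x = np.log([1.0 / s for s, _ in pts])
    y = np.log([c for _, c in pts])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def differential_boxcount_dimension(roi: VolumeROI) -> float:
    """Intensity fractal dimension by 3-D differential box counting.

    Within each spatial box of side s the intensity column count is
    ceil((max-min)/h) + 1 with box height h scaled so the full intensity
    range maps onto the grid extent; N(s) sums the column counts.
    """
    zmin, ymin, xmin = (idx.min() for idx in np.nonzero(roi.mask))
    zmax, ymax, xmax = (idx.max() for idx in np.nonzero(roi.mask))
    sub = roi.intensities[zmin : zmax + 1, ymin : ymax + 1, xmin : xmax + 1].copy()
    submask = roi.mask[zmin : zmax + 1, ymin : ymax + 1, xmin : xmax + 1]
    mean_val = roi.intensities[roi.mask].mean()
    sub[~submask] = mean_val
    lo, hi = sub.min(), sub.max()
    rng = hi - lo
    m = min(sub.shape)
    # geometric-ish ladder dense enough for small lesions
    sizes = [s for s in (2, 3, 4, 6, 8, 12, 16, 24, 32) if s <= max(2, m // 2)]
    if len(sizes) < 3:
        logger.info("DBC ladder has <3 points; dimension missing")
        return float("nan")
    counts = []
    for s in sizes:
        pad = [(0, (-n) % s) for n in sub.shape]
        b = np.pad(sub, pad, mode="edge")
        nz, ny, nx = (n // s for n in b.shape)
        blocks = b.reshape(nz, s, ny, s, nx, s)
        bmax = blocks.max(axis=(1, 3, 5))
        bmin = blocks.min(axis=(1, 3, 5))
        h = rng * s / max(sub.shape) if rng > 0 else 1.0
        n_cols = np.ceil((bmax - bmin) / h) + 1 if rng > 0 else np.ones_like(bmax)
        counts.append(float(n_cols.sum()))
    x = np.log([1.0 / s for s in sizes])
    y = np.log(counts)
    return float(np.polyfit(x, y, 1)[0])


def lacunarity(binary: np.ndarray, box_size: int = 3) -> float:
    """Gliding-box lacunarity of an occupancy field at a fixed box size.

    Lambda = var(mass)/mean(mass)^2 over all boxes fully inside the
    array; 0 for a homogeneous field.
    """
    binary = np.asarray(binary, dtype=np.float64)
    if any(n < box_size for n in binary.shape):
        return float("nan")
    mass = ndimage.uniform_filter(binary, size=box_size, mode="constant")
    k = box_size // 2
    core = mass[k : binary.shape[0] - k, k : binary.shape[1] - k, k : binary.shape[2] - k]
    mu = core.mean()
    if mu == 0:
        return float("nan")
    return float(core.var() / mu**2)


def fractal_features(roi: VolumeROI, lacunarity_box: int = 3) -> dict[str, float]:
    eroded = ndimage.binary_erosion(roi.mask)
    boundary = roi.mask & ~eroded
    zmin, ymin, xmin = (idx.min() for idx in np.nonzero(roi.mask))
    zmax, ymax, xmax = (idx.max() for idx in np.nonzero(roi.mask))
    submask = roi.mask[zmin : zmax + 1, ymin : ymax + 1, xmin : xmax + 1]
    return {
        "fractal_surface_dim": boxcount_dimension(
            boundary[zmin : zmax + 1, ymin : ymax + 1, xmin : xmax + 1]
        ),
        "fractal_dbc_dim": differential_boxcount_dimension(roi),
        "fractal_lacunarity": lacunarity(submask, box_size=lacunarity_box),
    }
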