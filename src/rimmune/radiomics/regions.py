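"""Peritumoral rim decomposition: inner core, outer rim, delta differences.

The tumor mask is split by metric erosion into an *inner* core and an
*outer* shell of depth ``rim_depth_mm``.  The *delta* distribution is
built by seeded random pairing of equal-sized subsamples of outer and
inner voxel intensities (elementwise outer minus inner), and *deltaS*
is a seeded subsample of delta.  Statistics of these distributions form
the ``(out)``, ``(delta)`` and ``(deltaS)`` feature variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from rimmune.volume import VolumeROI

__all__ = ["RegionSet", "decompose_regions"]


@dataclass
class RegionSet:
    """Inner/outer partition of a tumor mask plus paired-difference values."""

    inner_mask: np.ndarray
    outer_mask: np.ndarray
    delta_values: np.ndarray
    deltaS_values: np.ndarray
    rng_seed: int

    def __post_init__(self) -> None:
        if (self.inner_mask & self.outer_mask).any():
            raise ValueError("inner and outer masks overlap")
        if len(self.deltaS_values) > len(self.delta_values):
            raise ValueError("deltaS cannot exceed delta in size")


def decompose_regions(
    roi: VolumeROI,
    rim_depth_mm: float = 2.0,
    subsample_frac: float = 0.5,
    subsample_n: int | None = None,
    seed: int = 0,
) -> RegionSet:
    """Split the mask into inner core and outer rim of depth ``rim_depth_mm``.

    The erosion is metric-aware: a voxel is *inner* when its Euclidean
    distance (in mm, using the voxel spacing) to the nearest background
    voxel exceeds ``rim_depth_mm``.  Volume edges count as background.

    ``subsample_n`` (or ``subsample_frac`` of the delta size if not
    given) sets the deltaS subsample size; the pairing and subsampling
    are driven by ``seed``.
    """
    if rim_depth_mm <= 0:
        raise ValueError("rim_depth_mm must be > 0")
    padded = np.pad(roi.mask, 1)
    dist = ndimage.distance_transform_edt(padded, sampling=roi.spacing_mm)[1:-1, 1:-1, 1:-1]
    inner = dist > rim_depth_mm
    if not inner.any():
        raise ValueError(
            f"erosion by rim_depth_mm={rim_depth_mm} empties the inner region; "
            "use a smaller rim depth for this lesion"
        )
    outer = roi.mask & ~inner

    rng = np.random.default_rng(seed)
    # sort before pairing so the seeded draw depends only on the value
    # multisets, not on voxel traversal order (translation invariance)
    outer_vals = np.sort(roi.intensities[outer])
    inner_vals = np.sort(roi.intensities[inner])
    m = min(outer_vals.size, inner_vals.size)
    delta = rng.choice(outer_vals, size=m, replace=False) - rng.choice(
        inner_vals, size=m, replace=False
    )
    if subsample_n is None:
        subsample_n = max(1, int(round(subsample_frac * m)))
    subsample_n = min(subsample_n, m)
    deltaS = rng.choice(delta, size=subsample_n, replace=False)
    return RegionSet(
        inner_mask=inner,
        outer_mask=outer,
        delta_values=delta,
        deltaS_values=deltaS,
        rng_seed=seed,
    )
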