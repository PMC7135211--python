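"""Laplacian-of-Gaussian filter-bank features.

The volume is filtered with a scale-normalized LoG (sigma^2 * the
Gaussian-Laplace response) at each physical-unit sigma of the bank; the
filter sigma is converted to voxel units per axis from the spacing.
Nine first-order statistics of the in-mask response per sigma, over the
default seven-sigma bank, give 63 features.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from rimmune.radiomics.histogram import histogram_features
from rimmune.volume import VolumeROI

__all__ = ["DEFAULT_SIGMAS_MM", "LOG_STATS", "log_filter_response", "log_filter_features"]

DEFAULT_SIGMAS_MM = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5]

LOG_STATS = ["mean", "sd", "skewness", "kurtosis", "median", "min", "max", "entropy", "uniformity"]


def log_filter_response(roi: VolumeROI, sigma_mm: float) -> np.ndarray:
    """Scale-normalized LoG response of the intensity grid."""
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    if sigma_mm < 0.5 * min(roi.spacing_mm):
        warnings.warn(
            f"sigma {sigma_mm} mm is below half the smallest voxel dimension; "
            "response is dominated by the grid",
            stacklevel=2,
        )
    sigma_vox = [sigma_mm / s for s in roi.spacing_mm]
    resp = ndimage.gaussian_laplace(roi.intensities, sigma=sigma_vox, mode="nearest")
    # the sampled LoG kernel does not sum exactly to zero (visible at small
    # sigma); subtract the residual DC gain so constants map to zero exactly
    k = _kernel_dc_gain(sigma_vox)
    if k != 0.0:
        resp = resp - k * ndimage.gaussian_filter(roi.intensities, sigma=sigma_vox, mode="nearest")
    return sigma_mm**2 * resp


def _kernel_dc_gain(sigma_vox) -> float:
    """Sum of the sampled LoG kernel weights (its response to a constant 1)."""
    size = [2 * (int(4.0 * s + 0.5) + 1) + 1 for s in sigma_vox]
    probe = np.ones(size)
    center = tuple(n // 2 for n in size)
    return float(ndimage.gaussian_laplace(probe, sigma=sigma_vox, mode="nearest")[center])


def log_filter_features(
    roi: VolumeROI, sigmas_mm: list[float] | None = None
) -> dict[str, float]:
    """Per-sigma first-order statistics of the in-mask LoG response."""
    sigmas = DEFAULT_SIGMAS_MM if sigmas_mm is None else list(sigmas_mm)
    out: dict[str, float] = {}
    for s in sigmas:
        resp = log_filter_response(roi, s)[roi.mask]
        stats = histogram_features(resp, label=f"LoG sigma={s}")
        for name in LOG_STATS:
            out[f"log_s{s:g}_{name}"] = stats[name]
    return out
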