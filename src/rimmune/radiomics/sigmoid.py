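"""Sigmoid margin features: logistic fits of boundary-normal profiles.

Intensity profiles are sampled along outward surface normals through
seeded boundary points and fitted with a four-parameter logistic

    f(d) = b + A / (1 + exp((d - c) / s)),   s > 0,

so that ``A`` is the inside-minus-outside step height of the margin,
``s`` its width and ``c`` its position relative to the segmented
boundary.  Features are the mean and SD over converged fits of A, s
and c (six features).  A lesion with fewer than 20% converged profiles
yields all-missing features.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage, optimize

from rimmune.volume import VolumeROI

logger = logging.getLogger(__name__)

__all__ = ["SIGMOID_FEATURES", "fit_profile", "sigmoid_features"]

SIGMOID_FEATURES = [
    "sigmoid_amp_mean",
    "sigmoid_amp_sd",
    "sigmoid_width_mean",
    "sigmoid_width_sd",
    "sigmoid_center_mean",
    "sigmoid_center_sd",
]


def _logistic_step(d, b, A, c, s):
    return b + A / (1.0 + np.exp(np.clip((d - c) / s, -60, 60)))


def fit_profile(d: np.ndarray, y: np.ndarray) -> tuple[float, float, float] | None:
    """Least-squares logistic fit; returns (A, s, c) or None on failure."""
    if y.max() - y.min() < 1e-9:
        return None  # perfectly flat profile: no margin to fit
    inside = y[: max(2, len(y) // 4)].mean()
    outside = y[-max(2, len(y) // 4) :].mean()
    span = max(abs(y.max() - y.min()), 1e-6)
    p0 = [outside, inside - outside, 0.0, max(0.25 * (d[-1] - d[0]) / 8, 0.1)]
    try:
        popt, _ = optimize.curve_fit(
            _logistic_step,
            d,
            y,
            p0=p0,
            maxfev=400,
            bounds=(
                [-np.inf, -10 * span - 1e-3, d[0], 1e-3],
                [np.inf, 10 * span + 1e-3, d[-1], (d[-1] - d[0])],
            ),
        )
    except (RuntimeError, ValueError):
        return None
    b, A, c, s = popt
    return float(A), float(s), float(c)


def sigmoid_features(
    roi: VolumeROI,
    n_profiles: int = 30,
    profile_len_mm: float = 1.5,
    seed: int = 0,
    step_mm: float | None = None,
) -> dict[str, float]:
    """Fit margin profiles at seeded boundary points and summarize.

    Normals are taken from the gradient of a Gaussian-smoothed mask
    (pointing outward); intensities are sampled by trilinear
    interpolation at ``step_mm`` (default: half the smallest voxel
    dimension) over +-``profile_len_mm`` around each boundary point.
    """
    mask = roi.mask
    # border_value=1: voxels at the volume edge are not margin candidates
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=1)
    pts = np.argwhere(boundary)
    if pts.shape[0] == 0:
        raise ValueError("mask has no boundary voxels")
    rng = np.random.default_rng(seed)
    if pts.shape[0] > n_profiles:
        pts = pts[rng.choice(pts.shape[0], size=n_profiles, replace=False)]

    smooth = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.5)
    grad = np.stack(np.gradient(smooth, *roi.spacing_mm))
    if step_mm is None:
        step_mm = 0.5 * min(roi.spacing_mm)
    d = np.arange(-profile_len_mm, profile_len_mm + 1e-9, step_mm)

    spacing = np.asarray(roi.spacing_mm)
    results = []
    for p in pts:
        n = -grad[:, p[0], p[1], p[2]]  # outward: against the mask gradient
        norm = np.linalg.norm(n)
        if norm < 1e-9:
            continue
        n = n / norm
        # physical-space line, converted back to voxel coordinates
        coords = (p[None, :] * spacing[None, :] + d[:, None] * n[None, :]) / spacing[None, :]
        y = ndimage.map_coordinates(roi.intensities, coords.T, order=1, mode="nearest")
        fit = fit_profile(d, y)
        if fit is not None:
            results.append(fit)

    if len(results) < 0.2 * max(1, len(pts)):
        logger.info("only %d/%d sigmoid fits converged; features missing", len(results), len(pts))
        return {k: float("nan") for k in SIGMOID_FEATURES}
    arr = np.array(results)  # columns: A, s, c
    return {
        "sigmoid_amp_mean": float(arr[:, 0].mean()),
        "sigmoid_amp_sd": float(arr[:, 0].std()),
        "sigmoid_width_mean": float(arr[:, 1].mean()),
        "sigmoid_width_sd": float(arr[:, 1].std()),
        "sigmoid_center_mean": float(arr[:, 2].mean()),
        "sigmoid_center_sd": float(arr[:, 2].std()),
    }
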