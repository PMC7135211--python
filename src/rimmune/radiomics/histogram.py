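"""First-order (intensity histogram) statistics.

Population-moment conventions: variance is the second central moment
m2 = mean((x-mean)^2); skewness = m3 / m2^1.5; kurtosis is reported as
*excess* kurtosis m4 / m2^2 - 3.  Entropy and uniformity are computed
on a fixed-bin-count histogram over the value range.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["HISTOGRAM_STATS", "PERCENTILES", "histogram_features", "entropy_uniformity"]

HISTOGRAM_STATS = [
    "mean",
    "sd",
    "variance",
    "skewness",
    "kurtosis",
    "median",
    "min",
    "max",
    "entropy",
    "uniformity",
    "iqr",
]

PERCENTILES = [10, 25, 75, 90]


def entropy_uniformity(values: np.ndarray, bins: int = 32) -> tuple[float, float]:
    """Shannon entropy (bits) and uniformity of the binned value histogram.

    A constant input occupies a single bin: entropy 0, uniformity 1.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 0.0, 1.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum()), float((p**2).sum())


def histogram_features(
    values: np.ndarray, bins: int = 32, percentiles: bool = False, label: str = ""
) -> dict[str, float]:
    """First-order statistic map of an intensity sample.

    Zero-variance inputs yield NaN skewness/kurtosis (logged; downstream
    KNN imputation handles them).  With ``percentiles=True`` the p10,
    p25, p75 and p90 quantiles are appended.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    centered = values - mean
    m2 = np.mean(centered**2)
    out: dict[str, float] = {
        "mean": float(mean),
        "sd": float(np.sqrt(m2)),
        "variance": float(m2),
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "iqr": float(np.percentile(values, 75) - np.percentile(values, 25)),
    }
    if m2 > 0:
        out["skewness"] = float(np.mean(centered**3) / m2**1.5)
        out["kurtosis"] = float(np.mean(centered**4) / m2**2 - 3.0)
    else:
        logger.info("zero variance%s: skewness/kurtosis set to missing", f" ({label})" if label else "")
        out["skewness"] = float("nan")
        out["kurtosis"] = float("nan")
    out["entropy"], out["uniformity"] = entropy_uniformity(values, bins=bins)
    if percentiles:
        for p in PERCENTILES:
            out[f"p{p}"] = float(np.percentile(values, p))
    return out
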