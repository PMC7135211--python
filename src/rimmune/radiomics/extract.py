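"""Catalog-driven extraction of the full feature vector per lesion."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rimmune.radiomics.catalog import (
    FeatureCatalog,
    GLCM_DISTANCES,
    default_catalog,
)
from rimmune.radiomics.fractal import fractal_features
from rimmune.radiomics.histogram import histogram_features
from rimmune.radiomics.logfilter import log_filter_features
from rimmune.radiomics.regions import decompose_regions
from rimmune.radiomics.shape import shape_features
from rimmune.radiomics.sigmoid import sigmoid_features
from rimmune.radiomics.texture import (
    discretize,
    glcm_build,
    glcm_features,
    gldm_features,
    gldm_matrix,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)
from rimmune.volume import VolumeROI

__all__ = ["extract_all", "extract_table", "write_feature_table"]


def _physical_features(roi: VolumeROI) -> dict[str, float]:
    n_vox = int(roi.mask.sum())
    volume = n_vox * roi.voxel_volume_mm3
    mean_hu = float(roi.roi_values.mean())
    # water-calibrated mass surrogate: density ~ (HU + 1000)/1000 g/cm^3
    mass = volume * (mean_hu + 1000.0) / 1000.0
    slice_area = roi.spacing_mm[1] * roi.spacing_mm[2]
    max_axial = float(roi.mask.sum(axis=(1, 2)).max() * slice_area)
    return {
        "physical_volume_mm3": volume,
        "physical_mass_surrogate": mass,
        "physical_max_axial_area_mm2": max_axial,
    }


def extract_all(
    roi: VolumeROI,
    catalog: FeatureCatalog | None = None,
    seed: int = 0,
    rim_depth_mm: float = 2.0,
    levels: int = 32,
    n_profiles: int = 30,
    profile_len_mm: float = 1.5,
) -> dict[str, float]:
    """Compute one value (or NaN for legitimately missing) per catalog entry.

    Deterministic given (roi, catalog, seed): the seed drives the delta
    pairing/subsampling and the sigmoid profile selection.  Any
    non-finite value that is not an expected missing marker (infinite
    values) raises with the feature name.
    """
    if catalog is None:
        catalog = default_catalog()

    values: dict[str, float] = {}
    values.update(_physical_features(roi))

    regions = decompose_regions(roi, rim_depth_mm=rim_depth_mm, seed=seed)
    region_values = {
        "total": roi.roi_values,
        "inner": roi.intensities[regions.inner_mask],
        "outer": roi.intensities[regions.outer_mask],
        "delta": regions.delta_values,
        "deltaS": regions.deltaS_values,
    }
    for region, vals in region_values.items():
        stats = histogram_features(vals, percentiles=(region == "total"), label=region)
        for stat, v in stats.items():
            key = f"{stat}_{region}" if not stat.startswith("p") else f"{stat}_total"
            values[key] = v

    values.update(shape_features(roi.mask, roi.spacing_mm))

    disc, n_levels = discretize(roi.intensities, roi.mask, levels)
    for d in GLCM_DISTANCES:
        g = glcm_build(roi.intensities, roi.mask, distance_voxels=d, disc=disc, n_levels=n_levels)
        for stat, v in glcm_features(g).items():
            values[f"glcm_{stat}_d{d}"] = v
    for stat, v in glrlm_features(glrlm_matrix(disc, n_levels)).items():
        values[f"glrlm_{stat}"] = v
    for stat, v in glszm_features(glszm_matrix(disc, n_levels)).items():
        values[f"glszm_{stat}"] = v
    for stat, v in ngtdm_features(*ngtdm_table(disc, n_levels)).items():
        values[f"ngtdm_{stat}"] = v
    for stat, v in gldm_features(gldm_matrix(disc, n_levels)).items():
        values[f"gldm_{stat}"] = v

    values.update(log_filter_features(roi))
    values.update(fractal_features(roi))
    values.update(
        sigmoid_features(roi, n_profiles=n_profiles, profile_len_mm=profile_len_mm, seed=seed)
    )

    out: dict[str, float] = {}
    for entry in catalog.entries:
        if entry.feature_id not in values:
            raise KeyError(f"catalog entry {entry.feature_id!r} not produced by the extractor")
        v = values[entry.feature_id]
        if np.isinf(v):
            raise ValueError(f"feature {entry.feature_id!r} is non-finite (inf)")
        out[entry.feature_id] = float(v)
    return out


def extract_table(
    rois: dict[str, VolumeROI],
    catalog: FeatureCatalog | None = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Extract a samples x features table (index = sample_id)."""
    if catalog is None:
        catalog = default_catalog()
    rows = {sid: extract_all(roi, catalog=catalog, seed=seed, **kwargs) for sid, roi in rois.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[catalog.feature_ids()]


def write_feature_table(
    table: pd.DataFrame, path: str | Path, catalog: FeatureCatalog | None = None, seed: int = 0
) -> None:
    """Write the feature CSV plus a sidecar JSON with census and seed."""
    if catalog is None:
        catalog = default_catalog()
    path = Path(path)
    table.to_csv(path, index_label="sample_id")
    sidecar = {
        "census": catalog.census(),
        "n_features": len(catalog),
        "seed": seed,
        "catalog_version": catalog.version,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
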