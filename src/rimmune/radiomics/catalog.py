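"""The 239-feature catalog: identifiers, groups, regions and the census.

The catalog is data-driven: the default manifest is generated here and
can be written to / read from a YAML file, so the composition can be
re-aligned without touching extraction code.  The census invariant —
3 physical, 59 histogram, 10 shape, 95 local, 63 LoG filter, 3 fractal
and 6 sigmoid features, 239 in total — is enforced on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from rimmune.radiomics.histogram import HISTOGRAM_STATS, PERCENTILES
from rimmune.radiomics.logfilter import DEFAULT_SIGMAS_MM, LOG_STATS
from rimmune.radiomics.shape import SHAPE_FEATURES
from rimmune.radiomics.sigmoid import SIGMOID_FEATURES

__all__ = ["GROUP_CENSUS", "REGIONS", "CatalogEntry", "FeatureCatalog", "default_catalog"]

GROUP_CENSUS = {
    "physical": 3,
    "histogram": 59,
    "shape": 10,
    "local": 95,
    "log_filter": 63,
    "fractal": 3,
    "sigmoid": 6,
}

REGIONS = ["total", "inner", "outer", "delta", "deltaS"]

GLCM_STATS = [
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "joint_variance",
    "mcc",
]

GLRLM_STATS = [
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_variance",
    "run_entropy",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
]

GLSZM_STATS = [
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "size_zone_nonuniformity",
    "size_zone_nonuniformity_normalized",
    "zone_percentage",
    "gray_level_variance",
    "zone_variance",
    "zone_entropy",
    "low_gray_level_zone_emphasis",
    "high_gray_level_zone_emphasis",
    "small_area_low_gray_level_emphasis",
    "small_area_high_gray_level_emphasis",
    "large_area_low_gray_level_emphasis",
    "large_area_high_gray_level_emphasis",
]

NGTDM_STATS = ["coarseness", "contrast", "busyness", "complexity", "strength"]

GLDM_STATS = [
    "small_dependence_emphasis",
    "large_dependence_emphasis",
    "gray_level_nonuniformity",
    "dependence_nonuniformity",
    "dependence_entropy",
    "dependence_variance",
]

GLCM_DISTANCES = [1, 2]


@dataclass(frozen=True)
class CatalogEntry:
    feature_id: str
    group: str
    region: str = "n/a"
    parameters: dict = field(default_factory=dict)


@dataclass
class FeatureCatalog:
    """Ordered feature manifest with an enforced group census."""

    entries: list[CatalogEntry]
    version: str = "1"

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = {x for x in ids if ids.count(x) > 1}
            raise ValueError(f"duplicate feature ids: {sorted(dupes)}")
        census = self.census()
        if census != GROUP_CENSUS:
            raise ValueError(f"catalog census {census} != required {GROUP_CENSUS}")

    def census(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.group] = out.get(e.group, 0) + 1
        return out

    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "entries": [
                {
                    "feature_id": e.feature_id,
                    "group": e.group,
                    "region": e.region,
                    "parameters": e.parameters,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureCatalog":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        entries = [
            CatalogEntry(
                feature_id=e["feature_id"],
                group=e["group"],
                region=e.get("region", "n/a"),
                parameters=e.get("parameters", {}),
            )
            for e in payload["entries"]
        ]
        return cls(entries=entries, version=str(payload.get("version", "1")))


def default_catalog() -> FeatureCatalog:
    """Build the default 239-entry manifest."""
    entries: list[CatalogEntry] = []

    for fid in ["physical_volume_mm3", "physical_mass_surrogate", "physical_max_axial_area_mm2"]:
        entries.append(CatalogEntry(fid, "physical", "total"))

    for region in REGIONS:
        for stat in HISTOGRAM_STATS:
            entries.append(CatalogEntry(f"{stat}_{region}", "histogram", region))
    for p in PERCENTILES:
        entries.append(CatalogEntry(f"p{p}_total", "histogram", "total"))

    for fid in SHAPE_FEATURES:
        entries.append(CatalogEntry(fid, "shape", "total"))

    for d in GLCM_DISTANCES:
        for stat in GLCM_STATS:
            entries.append(
                CatalogEntry(f"glcm_{stat}_d{d}", "local", "total", {"distance": d})
            )
    for stat in GLRLM_STATS:
        entries.append(CatalogEntry(f"glrlm_{stat}", "local", "total"))
    for stat in GLSZM_STATS:
        entries.append(CatalogEntry(f"glszm_{stat}", "local", "total"))
    for stat in NGTDM_STATS:
        entries.append(CatalogEntry(f"ngtdm_{stat}", "local", "total"))
    for stat in GLDM_STATS:
        entries.append(CatalogEntry(f"gldm_{stat}", "local", "total"))

    for s in DEFAULT_SIGMAS_MM:
        for stat in LOG_STATS:
            entries.append(
                CatalogEntry(f"log_s{s:g}_{stat}", "log_filter", "total", {"sigma_mm": s})
            )

    for fid in ["fractal_surface_dim", "fractal_dbc_dim", "fractal_lacunarity"]:
        entries.append(CatalogEntry(fid, "fractal", "total"))

    for fid in SIGMOID_FEATURES:
        entries.append(CatalogEntry(fid, "sigmoid", "total"))

    return FeatureCatalog(entries=entries)
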