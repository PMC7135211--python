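"""Simulated expression matrices with planted immune-signature enrichment.

Expression values live on a log2-microarray-like scale: every gene has a
baseline drawn once per cohort, every measurement adds i.i.d. Gaussian
noise, and the member genes of each immune gene set receive an additive
per-sample shift proportional to that sample's latent activity for the
set.  Three designated sets (Th1 / Th2 / cytotoxic T cells) use the
latent levels carried by :class:`~rimmune.phantoms.LatentImmuneState`;
the remaining sets get their own independent latents so that a
28-signature panel has realistic, mutually independent structure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from gseapy.parser import read_gmt

from rimmune.phantoms import LatentImmuneState

__all__ = [
    "make_immune_gene_sets",
    "read_gene_sets",
    "write_gmt",
    "generate_expression",
    "write_expression_tsv",
    "read_expression_tsv",
]

#: canonical names for a 28-signature immune panel (synthetic stand-in
#: membership; the names follow the usual immune-cell signature naming)
PANEL_28 = [
    "Th1_cells",
    "Th2_cells",
    "Cytotoxic_cells",
    "Th17_cells",
    "Treg_cells",
    "T_helper_cells",
    "T_cells",
    "CD8_T_cells",
    "T_gamma_delta",
    "T_central_memory",
    "T_effector_memory",
    "T_follicular_helper",
    "B_cells",
    "NK_cells",
    "NK_CD56bright_cells",
    "NK_CD56dim_cells",
    "Dendritic_cells",
    "Activated_DC",
    "Immature_DC",
    "Plasmacytoid_DC",
    "Macrophages",
    "Mast_cells",
    "Neutrophils",
    "Eosinophils",
    "Monocytes",
    "Cancer_cells",
    "Endothelial_cells",
    "Fibroblasts",
]

DESIGNATED = {"th1": "Th1_cells", "th2": "Th2_cells", "ctl": "Cytotoxic_cells"}


def make_immune_gene_sets(
    n_genes: int = 5000, genes_per_set: int = 20, seed: int = 0
) -> dict[str, list[str]]:
    """Build a synthetic 28-set immune panel over a gene universe.

    Membership is assigned by seeded sampling without replacement within
    each set; different sets may overlap, as real signature collections
    do.  Gene ids are ``G000001`` ... style placeholders.
    """
    rng = np.random.default_rng(seed)
    universe = [f"G{i:06d}" for i in range(n_genes)]
    sets: dict[str, list[str]] = {}
    for name in PANEL_28:
        idx = rng.choice(n_genes, size=genes_per_set, replace=False)
        sets[name] = [universe[i] for i in sorted(idx)]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (delegates to gseapy's parser)."""
    return {k: list(v) for k, v in read_gmt(str(path)).items()}


def generate_expression(
    states: list[LatentImmuneState],
    gene_sets: dict[str, list[str]],
    base_noise: float = 1.0,
    seed: int = 0,
    effect_size: float = 2.0,
    n_genes: int = 5000,
    baseline_mean: float = 6.0,
    baseline_sd: float = 1.0,
    designated: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix with planted enrichment.

    Parameters
    ----------
    states
        Latent immune states; one sample (column) each.
    gene_sets
        Name -> member gene ids; must contain the three designated sets.
    base_noise
        SD of the per-measurement Gaussian noise (log2-scale units).
    effect_size
        Additive shift, in the same units, applied to member genes per
        unit of the corresponding latent level.
    designated
        Mapping with keys ``th1``/``th2``/``ctl`` naming the sets driven
        by the sample latents; defaults to the panel's canonical names.

    Returns
    -------
    pandas.DataFrame
        Non-negative matrix, index = gene ids, columns = sample ids.
    """
    if len(gene_sets) < 3:
        raise ValueError("gene_sets must contain at least 3 sets")
    designated = dict(DESIGNATED if designated is None else designated)
    for key, name in designated.items():
        if name not in gene_sets:
            raise KeyError(f"designated {key} set {name!r} absent from the collection")

    rng = np.random.default_rng(seed)
    member_genes = sorted({g for genes in gene_sets.values() for g in genes})
    universe = sorted(set(f"G{i:06d}" for i in range(n_genes)) | set(member_genes))
    gene_index = {g: i for i, g in enumerate(universe)}
    n_g, n_s = len(universe), len(states)

    baseline = baseline_mean + baseline_sd * rng.standard_normal(n_g)
    values = baseline[:, None] + (
        base_noise * rng.standard_normal((n_g, n_s)) if base_noise > 0 else 0.0
    )

    latent_by_key = {
        "th1": np.array([s.th1_level for s in states]),
        "th2": np.array([s.th2_level for s in states]),
        "ctl": np.array([s.ctl_level for s in states]),
    }
    designated_names = set(designated.values())
    for name, genes in gene_sets.items():
        if name in designated_names:
            key = next(k for k, v in designated.items() if v == name)
            levels = latent_by_key[key]
        else:
            # non-designated signatures fluctuate with their own latents
            levels = rng.standard_normal(n_s)
        rows = [gene_index[g] for g in genes]
        values[np.ix_(rows, range(n_s))] += effect_size * levels[None, :]

    values = np.clip(values, 0.0, None)
    return pd.DataFrame(values, index=universe, columns=[s.sample_id for s in states])


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df
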