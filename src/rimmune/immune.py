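"""Immune-microenvironment profiling: ssGSEA, PCA, mean-cutoff labels.

Each sample is scored for each immune gene set with single-sample gene
set enrichment analysis: genes are ranked by expression (descending;
ties broken by stable gene order), the ranked list is walked
accumulating the in-set weighted empirical CDF minus the out-of-set
uniform ECDF, and the score is the sum of the running differences
(an integrated enrichment statistic).  The in-set weight of a gene at
descending position p of n is ``(n - p + 1) ** alpha`` — a rank-based
weight, so scores depend on the expression values only through their
ordering.  ``alpha = 0`` gives the unweighted Kolmogorov-like walk.

Scores can be normalized by the global score range across the matrix.
Target signatures (Th1, Th2, cytotoxic T cells) are dichotomized into
high/low at the *cohort mean*; every cohort applies its own cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "ssgsea_score",
    "score_matrix",
    "PCAResult",
    "pca_signatures",
    "ImmuneLabelSet",
    "dichotomize",
]


def ssgsea_score(
    sample_expression: pd.Series | dict[str, float],
    gene_set: list[str],
    alpha: float = 0.25,
) -> float:
    """Integrated enrichment score of one gene set in one sample.

    Raises if the set covers every measured gene (the out-of-set ECDF
    would be undefined); returns NaN (logged) when no set gene is
    measured.
    """
    if not isinstance(sample_expression, pd.Series):
        sample_expression = pd.Series(sample_expression)
    genes = sample_expression.index.to_numpy()
    values = sample_expression.to_numpy(dtype=np.float64)
    in_set = np.isin(genes, np.asarray(list(gene_set)))
    m = int(in_set.sum())
    if m == 0:
        logger.info("gene set has no overlap with measured genes; score missing")
        return float("nan")
    if m == len(genes):
        raise ValueError("gene set covers all measured genes; out-of-set ECDF undefined")

    # descending by value, ties by original (stable) gene order
    order = np.argsort(-values, kind="stable")
    in_sorted = in_set[order]
    n = len(genes)
    rank_stat = (n - np.arange(n)).astype(np.float64)  # n, n-1, ..., 1
    w = np.where(in_sorted, rank_stat**alpha, 0.0)
    p_in = np.cumsum(w)
    p_in /= p_in[-1]
    p_out = np.cumsum(np.where(in_sorted, 0.0, 1.0)) / (n - m)
    return float(np.sum(p_in - p_out))


def score_matrix(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA scores for every sample x gene set (samples x signatures).

    ``expr`` is genes x samples.  With ``normalize`` the whole matrix is
    divided by its global max - min (the usual ssGSEA normalization).
    """
    scores = pd.DataFrame(
        {
            name: [ssgsea_score(expr[s], genes, alpha=alpha) for s in expr.columns]
            for name, genes in sets.items()
        },
        index=expr.columns,
    )
    if normalize:
        rng = np.nanmax(scores.values) - np.nanmin(scores.values)
        if rng > 0:
            scores = scores / rng
    return scores


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # signatures x components
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def pca_signatures(m: pd.DataFrame, k: int = 2) -> PCAResult:
    """Column-centered PCA of the signature score matrix.

    Sign convention: each component's largest-|loading| entry is made
    positive.  ``k`` greater than the matrix rank is truncated with a
    warning.
    """
    rank = int(np.linalg.matrix_rank(m.values - m.values.mean(axis=0)))
    if k > rank:
        logger.warning("k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    pca = PCA(n_components=k)
    scores = pca.fit_transform(m.values)
    loadings = pca.components_.T.copy()  # signatures x k
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=m.columns, columns=cols),
        scores=pd.DataFrame(scores, index=m.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class ImmuneLabelSet:
    """High/low labels for one target signature in one cohort."""

    labels: pd.Series  # sample_id -> "high" | "low"
    cutoff: float
    cohort_id: str
    target: str = ""

    @property
    def binary(self) -> pd.Series:
        """1 for high, 0 for low (high is the positive class)."""
        return (self.labels == "high").astype(int)


def dichotomize(scores: pd.Series, cohort_id: str, target: str = "") -> ImmuneLabelSet:
    """Label each sample high/low at this cohort's own mean score."""
    values = scores.to_numpy(dtype=np.float64)
    if np.allclose(values, values[0]):
        raise ValueError(f"degenerate split: all scores equal in cohort {cohort_id!r}")
    cutoff = float(values.mean())
    labels = pd.Series(np.where(values > cutoff, "high", "low"), index=scores.index)
    return ImmuneLabelSet(labels=labels, cutoff=cutoff, cohort_id=cohort_id, target=target)
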