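"""Local texture features from gray-level matrices.

Five matrix families over a discretized ROI: co-occurrence (GLCM),
run-length (GLRLM), size-zone (GLSZM), neighborhood tone difference
(NGTDM) and dependence (GLDM).  All use the 13 unique 3-D directions
(GLCM/GLRLM) or the full 26-neighborhood (GLSZM zones, NGTDM, GLDM),
counts restricted to voxel pairs inside the mask, and matrices merged
over directions before statistics are taken.

Gray levels are obtained by equal-width binning of the in-mask
intensities over their min-max range (fixed bin count, default 32); a
constant ROI collapses to a single level by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "OFFSETS_13",
    "discretize",
    "GLCM",
    "glcm_build",
    "glcm_features",
    "imc",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_table",
    "ngtdm_features",
    "gldm_matrix",
    "gldm_features",
]

#: the 13 unique 3-D direction offsets (half of the 26-neighborhood)
OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
]


def discretize(intensities: np.ndarray, mask: np.ndarray, levels: int = 32) -> tuple[np.ndarray, int]:
    """Equal-width binning of in-mask intensities into ``levels`` bins.

    Returns (grid of bin indices with -1 outside the mask, actual number
    of levels).  A constant ROI maps to a single level.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vals = intensities[mask]
    lo, hi = vals.min(), vals.max()
    disc = np.full(intensities.shape, -1, dtype=np.int64)
    if hi == lo:
        disc[mask] = 0
        return disc, 1
    idx = np.floor((intensities - lo) / (hi - lo) * levels).astype(np.int64)
    np.clip(idx, 0, levels - 1, out=idx)
    disc[~mask] = -1
    disc[mask] = idx[mask]
    return disc, levels


@dataclass
class GLCM:
    """Symmetrized, normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray  # levels x levels, sums to 1
    levels: int
    distance: int
    offsets: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GLCM matrix must be square")
        if (self.matrix < 0).any():
            raise ValueError("GLCM entries must be nonnegative")


def _pair_slices(off: tuple[int, int, int], shape: tuple[int, ...]):
    """Slices selecting (source, destination) positions for an offset."""
    src, dst = [], []
    for o, n in zip(off, shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_build(
    intensities: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    distance_voxels: int = 1,
    disc: np.ndarray | None = None,
    n_levels: int | None = None,
) -> GLCM:
    """Accumulate the co-occurrence matrix over the 13 unique directions.

    Both voxels of a pair must lie inside the mask.  The matrix is
    symmetrized (each pair counted in both orders) and normalized to
    sum 1.
    """
    if distance_voxels < 1:
        raise ValueError("distance_voxels must be >= 1")
    if disc is None:
        disc, n_levels = discretize(intensities, mask, levels)
    assert n_levels is not None
    L = n_levels
    counts = np.zeros((L, L), dtype=np.float64)
    offsets = [tuple(distance_voxels * o for o in off) for off in OFFSETS_13]
    for off in offsets:
        src, dst = _pair_slices(off, disc.shape)
        a, b = disc[src].ravel(), disc[dst].ravel()
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        counts += np.bincount(a[ok] * L + b[ok], minlength=L * L).reshape(L, L)
    counts = counts + counts.T
    total = counts.sum()
    if total > 0:
        counts /= total
    else:
        # single in-mask voxel, no pairs: point mass by convention
        counts = np.zeros((L, L))
        counts[0, 0] = 1.0
    return GLCM(matrix=counts, levels=L, distance=distance_voxels, offsets=offsets)


def imc(g: GLCM) -> float:
    """Informational measure of correlation (IMC1, log base 2).

    IMC1 = (HXY - HXY1) / max(HX, HY) with the 0*log(0) = 0 convention;
    returns 0 when both marginal entropies vanish (point-mass matrix).
    """
    p = g.matrix
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    prod = np.outer(px, py)
    nz1 = nz & (prod > 0)
    hxy1 = float(-(p[nz1] * np.log2(prod[nz1])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    denom = max(hx, hy)
    if denom == 0:
        return 0.0
    return (hxy - hxy1) / denom


def glcm_features(g: GLCM) -> dict[str, float]:
    """The 26 co-occurrence statistics (IBSI-style definitions)."""
    p = g.matrix
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(L, dtype=np.float64)  # |i-j| in 0..L-1
    p_diff = np.zeros(L)
    k_sum = np.arange(2, 2 * L + 1, dtype=np.float64)  # i+j in 2..2L
    p_sum = np.zeros(2 * L - 1)
    absd = np.abs(ii - jj).astype(np.int64)
    sumd = (ii + jj).astype(np.int64)
    np.add.at(p_diff, absd.ravel() - 0, p.ravel())
    np.add.at(p_sum, sumd.ravel() - 2, p.ravel())

    nz = p > 0
    ent = float(-(p[nz] * np.log2(p[nz])).sum())
    out: dict[str, float] = {}
    out["autocorrelation"] = float((ii * jj * p).sum())
    out["joint_average"] = mu_x
    out["cluster_prominence"] = float(((ii + jj - mu_x - mu_y) ** 4 * p).sum())
    out["cluster_shade"] = float(((ii + jj - mu_x - mu_y) ** 3 * p).sum())
    out["cluster_tendency"] = float(((ii + jj - mu_x - mu_y) ** 2 * p).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        out["correlation"] = 1.0
    da = float((k_diff * p_diff).sum())
    out["difference_average"] = da
    nzd = p_diff > 0
    out["difference_entropy"] = float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum())
    out["difference_variance"] = float(((k_diff - da) ** 2 * p_diff).sum())
    out["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["joint_energy"] = float((p**2).sum())
    out["joint_entropy"] = ent
    out["imc1"] = imc(g)
    # IMC2 = sqrt(1 - exp(-2 (HXY2 - HXY)))
    prod = np.outer(px, py)
    nz2 = prod > 0
    hxy2 = float(-(prod[nz2] * np.log2(prod[nz2])).sum())
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))))
    out["idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["idmn"] = float((p / (1.0 + ((ii - jj) / L) ** 2)).sum())
    out["id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    out["idn"] = float((p / (1.0 + np.abs(ii - jj) / L)).sum())
    offdiag = ii != jj
    out["inverse_variance"] = float((p[offdiag] / (ii - jj)[offdiag] ** 2).sum())
    out["maximum_probability"] = float(p.max())
    sa = float((k_sum * p_sum).sum())
    out["sum_average"] = sa
    nzs = p_sum > 0
    out["sum_entropy"] = float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum())
    out["sum_variance"] = float(((k_sum - sa) ** 2 * p_sum).sum())
    out["joint_variance"] = float(((ii - mu_x) ** 2 * p).sum())
    out["mcc"] = _max_correlation_coefficient(p, px, py)
    return out


def _max_correlation_coefficient(p: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j)=sum_k p_ik p_jk/(px_i py_k)."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    ps = p[np.ix_(keep, keep)]
    pxs = px[keep]
    pys = py[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = ps / pys[None, :]
        w[~np.isfinite(w)] = 0.0
        q = (ps / pxs[:, None]) @ w.T
    try:
        ev = np.linalg.eigvals(q)
    except np.linalg.LinAlgError:
        return 1.0
    ev = np.sort(np.abs(ev))
    if ev.size < 2:
        return 1.0
    return float(np.sqrt(max(0.0, min(1.0, ev[-2]))))


# ---------------------------------------------------------------------------
# run-length matrix (GLRLM)
# ---------------------------------------------------------------------------

def glrlm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Gray-level run-length matrix merged over the 13 directions.

    Entry (i, j-1): number of maximal runs of gray level i+1 and length
    j along any direction; out-of-mask voxels terminate runs.
    """
    shape = disc.shape
    max_run = int(max(shape))
    counts = np.zeros((n_levels, max_run), dtype=np.float64)
    grid = np.indices(shape)
    for off in OFFSETS_13:
        # line starts: voxels whose predecessor along the offset is out of grid
        pred_ok = np.ones(shape, dtype=bool)
        for ax, o in enumerate(off):
            if o != 0:
                c = grid[ax] - o
                pred_ok &= (c >= 0) & (c < shape[ax])
        starts = np.argwhere(~pred_ok)
        t = np.arange(max_run)
        pos = starts[:, None, :] + t[None, :, None] * np.array(off)[None, None, :]
        valid = np.ones(pos.shape[:2], dtype=bool)
        for ax in range(3):
            valid &= (pos[:, :, ax] >= 0) & (pos[:, :, ax] < shape[ax])
        vals = np.full(pos.shape[:2], -1, dtype=np.int64)
        vz = pos[..., 0].clip(0, shape[0] - 1)
        vy = pos[..., 1].clip(0, shape[1] - 1)
        vx = pos[..., 2].clip(0, shape[2] - 1)
        vals[valid] = disc[vz, vy, vx][valid]
        # row-wise run-length encoding via a separator column
        sep = np.full((vals.shape[0], 1), -2, dtype=np.int64)
        flat = np.concatenate([vals, sep], axis=1).ravel()
        change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
        run_starts = np.concatenate([[0], change])
        run_lens = np.diff(np.concatenate([run_starts, [flat.size]]))
        run_vals = flat[run_starts]
        keep = run_vals >= 0
        np.add.at(counts, (run_vals[keep], run_lens[keep] - 1), 1.0)
    return counts


def glrlm_features(counts: np.ndarray) -> dict[str, float]:
    n_r = counts.sum()
    if n_r == 0:
        return {k: float("nan") for k in _GLRLM_NAMES}
    i = np.arange(1, counts.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    p = counts / n_r
    n_p = float((counts * j).sum())
    r_i = counts.sum(axis=1)
    r_j = counts.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p > 0
    out = {
        "short_run_emphasis": float((counts / j**2).sum() / n_r),
        "long_run_emphasis": float((counts * j**2).sum() / n_r),
        "gray_level_nonuniformity": float((r_i**2).sum() / n_r),
        "gray_level_nonuniformity_normalized": float((r_i**2).sum() / n_r**2),
        "run_length_nonuniformity": float((r_j**2).sum() / n_r),
        "run_length_nonuniformity_normalized": float((r_j**2).sum() / n_r**2),
        "run_percentage": float(n_r / n_p),
        "gray_level_variance": float((p * (i - mu_i) ** 2).sum()),
        "run_variance": float((p * (j - mu_j) ** 2).sum()),
        "run_entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "low_gray_level_run_emphasis": float((counts / i**2).sum() / n_r),
        "high_gray_level_run_emphasis": float((counts * i**2).sum() / n_r),
        "short_run_low_gray_level_emphasis": float((counts / (i**2 * j**2)).sum() / n_r),
        "short_run_high_gray_level_emphasis": float((counts * i**2 / j**2).sum() / n_r),
        "long_run_low_gray_level_emphasis": float((counts * j**2 / i**2).sum() / n_r),
        "long_run_high_gray_level_emphasis": float((counts * i**2 * j**2).sum() / n_r),
    }
    return out


_GLRLM_NAMES = [
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


# ---------------------------------------------------------------------------
# size-zone matrix (GLSZM)
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Gray-level size-zone matrix (26-connected zones per level)."""
    n_vox = int((disc >= 0).sum())
    counts = np.zeros((n_levels, max(1, n_vox)), dtype=np.float64)
    for g in range(n_levels):
        labeled, n_zones = ndimage.label(disc == g, structure=_STRUCT_26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        np.add.at(counts, (g, sizes - 1), 1.0)
    return counts


def glszm_features(counts: np.ndarray) -> dict[str, float]:
    n_z = counts.sum()
    names = [
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
    if n_z == 0:
        return {k: float("nan") for k in names}
    i = np.arange(1, counts.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    p = counts / n_z
    n_p = float((counts * j).sum())
    z_i = counts.sum(axis=1)
    z_j = counts.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nz = p > 0
    vals = [
        float((counts / j**2).sum() / n_z),
        float((counts * j**2).sum() / n_z),
        float((z_i**2).sum() / n_z),
        float((z_i**2).sum() / n_z**2),
        float((z_j**2).sum() / n_z),
        float((z_j**2).sum() / n_z**2),
        float(n_z / n_p),
        float((p * (i - mu_i) ** 2).sum()),
        float((p * (j - mu_j) ** 2).sum()),
        float(-(p[nz] * np.log2(p[nz])).sum()),
        float((counts / i**2).sum() / n_z),
        float((counts * i**2).sum() / n_z),
        float((counts / (i**2 * j**2)).sum() / n_z),
        float((counts * i**2 / j**2).sum() / n_z),
        float((counts * j**2 / i**2).sum() / n_z),
        float((counts * i**2 * j**2).sum() / n_z),
    ]
    return dict(zip(names, vals))


# ---------------------------------------------------------------------------
# neighborhood gray-tone difference matrix (NGTDM)
# ---------------------------------------------------------------------------

def ngtdm_table(disc: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level (n_i, s_i): occurrence counts and summed tone differences.

    The neighborhood is the 26-neighborhood restricted to in-mask
    voxels; voxels with no in-mask neighbor are excluded.
    """
    inmask = disc >= 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nbr_count = ndimage.convolve(inmask.astype(np.float64), kernel, mode="constant")
    vals = np.where(inmask, disc, 0).astype(np.float64)
    nbr_sum = ndimage.convolve(vals, kernel, mode="constant")
    use = inmask & (nbr_count > 0)
    avg = np.zeros_like(vals)
    avg[use] = nbr_sum[use] / nbr_count[use]
    diff = np.abs(disc - avg)
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    g = disc[use]
    np.add.at(n_i, g, 1.0)
    np.add.at(s_i, g, diff[use])
    return n_i, s_i


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    n = n_i.sum()
    names = ["coarseness", "contrast", "busyness", "complexity", "strength"]
    if n == 0:
        return {k: float("nan") for k in names}
    p = n_i / n
    present = n_i > 0
    levels = np.arange(1, len(n_i) + 1, dtype=np.float64)
    ngp = int(present.sum())
    dens = float((p * s_i).sum())
    coarseness = 1.0 / dens if dens > 0 else 1e6
    if ngp > 1:
        pi = p[present][:, None]
        pj = p[present][None, :]
        li = levels[present][:, None]
        lj = levels[present][None, :]
        contrast = float((pi * pj * (li - lj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / n)
        denom_b = float(np.abs(li * pi - lj * pj).sum())
        busyness = dens / denom_b if denom_b > 0 else 0.0
        si = s_i[present][:, None]
        sj = s_i[present][None, :]
        complexity = float((np.abs(li - lj) * (pi * si + pj * sj) / (pi + pj)).sum() / n)
        s_tot = s_i.sum()
        strength = float(((pi + pj) * (li - lj) ** 2).sum() / s_tot) if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return dict(zip(names, [coarseness, contrast, busyness, complexity, strength]))


# ---------------------------------------------------------------------------
# dependence matrix (GLDM)
# ---------------------------------------------------------------------------

_OFFSETS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def gldm_matrix(disc: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P(i, k): gray level i, dependence size k.

    The dependence size of a voxel is 1 (itself) plus the number of
    in-mask 26-neighbors whose gray level differs by at most ``alpha``.
    """
    inmask = disc >= 0
    dep = np.ones(disc.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        src, dst = _pair_slices(off, disc.shape)
        sim = np.zeros(disc.shape, dtype=bool)
        sim[src] = inmask[src] & inmask[dst] & (np.abs(disc[src] - disc[dst]) <= alpha)
        dep += sim
    counts = np.zeros((n_levels, 27), dtype=np.float64)
    np.add.at(counts, (disc[inmask], dep[inmask] - 1), 1.0)
    return counts


def gldm_features(counts: np.ndarray) -> dict[str, float]:
    n = counts.sum()
    names = [
        "small_dependence_emphasis",
        "large_dependence_emphasis",
        "gray_level_nonuniformity",
        "dependence_nonuniformity",
        "dependence_entropy",
        "dependence_variance",
    ]
    if n == 0:
        return {k: float("nan") for k in names}
    i = np.arange(1, counts.shape[0] + 1, dtype=np.float64)[:, None]
    k = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    p = counts / n
    nz = p > 0
    mu_k = float((p * k).sum())
    vals = [
        float((counts / k**2).sum() / n),
        float((counts * k**2).sum() / n),
        float((counts.sum(axis=1) ** 2).sum() / n),
        float((counts.sum(axis=0) ** 2).sum() / n),
        float(-(p[nz] * np.log2(p[nz])).sum()),
        float((p * (k - mu_k) ** 2).sum()),
    ]
    return dict(zip(names, vals))
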