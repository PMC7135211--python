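"""Independent brute-force oracles for texture matrices and ssGSEA.

Everything here is written as plain nested loops over voxels/genes,
deliberately sharing no code with the package implementations, and is
only usable at toy sizes.
"""

from __future__ import annotations

import numpy as np

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


def _in(shape, p):
    return all(0 <= p[a] < shape[a] for a in range(3))


def glcm_bruteforce(disc: np.ndarray, n_levels: int, distance: int = 1) -> np.ndarray:
    """Double loop over all in-mask voxel pairs at each offset; symmetrized, normalized."""
    shape = disc.shape
    counts = np.zeros((n_levels, n_levels))
    for off in OFFSETS_13:
        d = tuple(distance * o for o in off)
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    if disc[z, y, x] < 0:
                        continue
                    q = (z + d[0], y + d[1], x + d[2])
                    if _in(shape, q) and disc[q] >= 0:
                        counts[disc[z, y, x], disc[q]] += 1
                        counts[disc[q], disc[z, y, x]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def glrlm_bruteforce(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Walk every line in every direction, recording maximal runs."""
    shape = disc.shape
    max_run = max(shape)
    counts = np.zeros((n_levels, max_run))
    for off in OFFSETS_13:
        for z in range(shape[0]):
            for y in range(shape[1]):
                for x in range(shape[2]):
                    prev = (z - off[0], y - off[1], x - off[2])
                    if _in(shape, prev):
                        continue  # not a line start
                    p = (z, y, x)
                    run_val, run_len = None, 0
                    while _in(shape, p):
                        v = disc[p]
                        if v >= 0 and v == run_val:
                            run_len += 1
                        else:
                            if run_val is not None and run_val >= 0:
                                counts[run_val, run_len - 1] += 1
                            run_val, run_len = (v, 1) if v >= 0 else (None, 0)
                        p = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                    if run_val is not None and run_val >= 0:
                        counts[run_val, run_len - 1] += 1
    return counts


def glszm_bruteforce(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Depth-first flood fill per gray level with 26-connectivity."""
    shape = disc.shape
    n_vox = int((disc >= 0).sum())
    counts = np.zeros((n_levels, max(1, n_vox)))
    seen = np.zeros(shape, dtype=bool)
    nbrs = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if disc[z, y, x] < 0 or seen[z, y, x]:
                    continue
                g = disc[z, y, x]
                stack, size = [(z, y, x)], 0
                seen[z, y, x] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in nbrs:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if _in(shape, q) and not seen[q] and disc[q] == g:
                            seen[q] = True
                            stack.append(q)
                counts[g, size - 1] += 1
    return counts


def ngtdm_bruteforce(disc: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    shape = disc.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if disc[z, y, x] < 0:
                    continue
                vals = []
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        for c in (-1, 0, 1):
                            if (a, b, c) == (0, 0, 0):
                                continue
                            q = (z + a, y + b, x + c)
                            if _in(shape, q) and disc[q] >= 0:
                                vals.append(disc[q])
                if vals:
                    g = disc[z, y, x]
                    n_i[g] += 1
                    s_i[g] += abs(g - sum(vals) / len(vals))
    return n_i, s_i


def gldm_bruteforce(disc: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    shape = disc.shape
    counts = np.zeros((n_levels, 27))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if disc[z, y, x] < 0:
                    continue
                dep = 1
                for a in (-1, 0, 1):
                    for b in (-1, 0, 1):
                        for c in (-1, 0, 1):
                            if (a, b, c) == (0, 0, 0):
                                continue
                            q = (z + a, y + b, x + c)
                            if _in(shape, q) and disc[q] >= 0 and abs(disc[q] - disc[z, y, x]) <= alpha:
                                dep += 1
                counts[disc[z, y, x], dep - 1] += 1
    return counts


def ssgsea_bruteforce(genes: list[str], values: list[float], gene_set: set[str], alpha: float) -> float:
    """Literal ranked-walk enumeration of the integrated enrichment score."""
    order = sorted(range(len(genes)), key=lambda i: (-values[i], i))
    n = len(genes)
    m = sum(1 for g in genes if g in gene_set)
    w_total = sum((n - pos) ** alpha for pos, i in enumerate(order) if genes[i] in gene_set)
    score, p_in, p_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        if genes[i] in gene_set:
            p_in += (n - pos) ** alpha / w_total
        else:
            p_out += 1.0 / (n - m)
        score += p_in - p_out
    return score
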