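"""Independent brute-force oracles used to validate the metric suite.

These deliberately avoid the implementation's code paths: boundaries come
from explicit neighbor loops, distances from full pairwise matrices, and
percentiles from sorted enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_dice(g: np.ndarray, p: np.ndarray) -> float:
    g = np.asarray(g, bool)
    p = np.asarray(p, bool)
    inter = 0
    ng = npp = 0
    for idx in np.ndindex(g.shape):
        if g[idx]:
            ng += 1
        if p[idx]:
            npp += 1
        if g[idx] and p[idx]:
            inter += 1
    if ng + npp == 0:
        return 1.0
    return 2.0 * inter / (ng + npp)


def brute_volsim(g, p, spacing=(1.0, 1.0, 1.0)) -> float:
    vox = float(np.prod(spacing))
    vg = float(np.asarray(g, bool).sum()) * vox
    vp = float(np.asarray(p, bool).sum()) * vox
    return 1.0 - abs(vg - vp) / (vg + vp)


def brute_boundary(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    mask = np.asarray(mask, bool)
    pts = []
    for idx in np.argwhere(mask):
        i, j, k = idx
        on_surface = False
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (
                0 <= ni < mask.shape[0]
                and 0 <= nj < mask.shape[1]
                and 0 <= nk < mask.shape[2]
            ):
                on_surface = True
                break
            if not mask[ni, nj, nk]:
                on_surface = True
                break
        if on_surface:
            pts.append(idx)
    return np.asarray(pts, float) * np.asarray(spacing)


def brute_hausdorff(g, p, spacing=(1.0, 1.0, 1.0), percentile=100.0) -> float:
    bg = brute_boundary(g, spacing)
    bp = brute_boundary(p, spacing)
    d = cdist(bp, bg)
    pooled = np.sort(np.concatenate([d.min(axis=1), d.min(axis=0)]))
    if percentile >= 100.0:
        return float(pooled[-1])
    rank = int(np.ceil(percentile / 100.0 * pooled.size)) - 1
    return float(pooled[max(rank, 0)])


def exact_wilcoxon_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    t_plus_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    obs_dev = abs(t_plus_obs - mean)
    count = 0
    total = 2 ** n
    for bits in range(total):
        t_plus = sum(ranks[i] for i in range(n) if (bits >> i) & 1)
        if abs(t_plus - mean) >= obs_dev - 1e-12:
            count += 1
    return count / total
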