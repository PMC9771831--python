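"""Segmentation evaluation: Dice, Hausdorff distances, volume similarity,
test-retest ICC, per-structure reporting, and paired comparisons.

Conventions for degenerate inputs are explicit and distinct:

* Dice of two empty masks is defined as 1.0 (perfect agreement on absence);
* volume similarity of two empty masks is undefined (rejected);
* Hausdorff distances require both masks nonempty; in per-structure
  reports, structures missing from either map carry NaN distances and are
  excluded from macro means, with the exclusion counted.

Hausdorff distances are computed on boundary voxels (mask voxels with at
least one 6-connected non-mask neighbor), voxel-center to voxel-center, in
mm.  The robust variant (HD95) is the nearest-rank 95th percentile of the
pooled set of both directed minimum-distance sets; the pooled set is the
union of the two directed sets, so HD95 <= HD always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import LabelMap
from .protocol import REGION_NAMES, LabelProtocol, aggregate_regions

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice(g: np.ndarray, p: np.ndarray) -> float:
    """Dice overlap 2|G∩P| / (|G|+|P|); both-empty is defined as 1.0."""
    g = np.asarray(g, bool)
    p = np.asarray(p, bool)
    if g.shape != p.shape:
        raise ValueError(f"grid mismatch: {g.shape} vs {p.shape}")
    denom = int(g.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((g & p).sum()) / denom


def volume_similarity(
    g: np.ndarray, p: np.ndarray,
    spacing_g: tuple[float, float, float] = (1.0, 1.0, 1.0),
    spacing_p: tuple[float, float, float] | None = None,
) -> float:
    """Volume similarity 1 - |V_G - V_P| / (V_G + V_P), in mm^3.

    Overlap-free: masks may live on different grids since only volumes
    enter.  Undefined (rejected) when both volumes are zero.
    """
    if spacing_p is None:
        spacing_p = spacing_g
    vg = float(np.asarray(g, bool).sum()) * float(np.prod(spacing_g))
    vp = float(np.asarray(p, bool).sum()) * float(np.prod(spacing_p))
    if vg + vp == 0:
        raise ValueError("volume similarity undefined: both masks are empty")
    return 1.0 - abs(vg - vp) / (vg + vp)


def boundary_voxels(
    mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> np.ndarray:
    """Coordinates (mm) of mask voxels with a 6-connected non-mask neighbor.

    Voxels on the grid face count as boundary (the outside is non-mask).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot extract the boundary of an empty mask")
    interior = ndimage.binary_erosion(mask, _FACE_STRUCT, border_value=0)
    surf = mask & ~interior
    coords = np.argwhere(surf).astype(float)
    return coords * np.asarray(spacing)


def hausdorff(
    g: np.ndarray,
    p: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    percentile: float = 100.0,
) -> float:
    """(Robust) symmetric Hausdorff distance between mask boundaries, in mm.

    The pooled distance set D is the union of both directed sets
    {min_g d(p, g)} and {min_p d(g, p)}.  ``percentile=100`` gives the
    classical maximum; ``percentile=95`` the robust nearest-rank 95th
    percentile of D.
    """
    g = np.asarray(g, bool)
    p = np.asarray(p, bool)
    if g.shape != p.shape:
        raise ValueError(f"grid mismatch: {g.shape} vs {p.shape}")
    if not g.any() or not p.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    bg = boundary_voxels(g, spacing)
    bp = boundary_voxels(p, spacing)
    d_p_to_g = cKDTree(bg).query(bp, k=1)[0]
    d_g_to_p = cKDTree(bp).query(bg, k=1)[0]
    pooled = np.concatenate([d_p_to_g, d_g_to_p])
    if percentile >= 100.0:
        return float(pooled.max())
    # nearest-rank percentile: smallest d with at least q*n values <= d
    pooled.sort()
    rank = int(np.ceil(percentile / 100.0 * pooled.size)) - 1
    return float(pooled[max(rank, 0)])


@dataclass(frozen=True)
class MetricRow:
    structure_id: int
    name: str
    dice: float
    volsim: float
    hd_mm: float
    hd95_mm: float
    present_gt: bool
    present_pred: bool


def per_structure_report(
    gt: LabelMap, pred: LabelMap, protocol: LabelProtocol
) -> pd.DataFrame:
    """Per-structure metric table plus merged regions and macro means.

    One row per protocol structure, then one per merged evaluation region
    (left/right gray matter, vermis, left/right white matter), then a
    ``macro_mean`` row averaging the 27 structure rows that are present in
    both maps.  Distances for structures missing from either map are NaN.
    """
    if gt.shape != pred.shape or tuple(gt.spacing) != tuple(pred.spacing):
        raise ValueError("ground truth and prediction must share grid and spacing")
    rows = []

    def one(lab_id: int, name: str, gdata: np.ndarray, pdata: np.ndarray) -> MetricRow:
        gm = gdata == lab_id
        pm = pdata == lab_id
        pg, pp = bool(gm.any()), bool(pm.any())
        d = dice(gm, pm)
        vs = volume_similarity(gm, pm, gt.spacing) if (pg or pp) else np.nan
        if pg and pp:
            hd = hausdorff(gm, pm, gt.spacing, 100.0)
            hd95 = hausdorff(gm, pm, gt.spacing, 95.0)
        else:
            hd = hd95 = np.nan
        return MetricRow(lab_id, name, d, vs, hd, hd95, pg, pp)

    for s in protocol.structures:
        rows.append(one(s.label_id, s.name, gt.data, pred.data))
    gt_m = aggregate_regions(gt, protocol)
    pr_m = aggregate_regions(pred, protocol)
    for rid, rname in REGION_NAMES.items():
        row = one(rid, rname, gt_m.data, pr_m.data)
        # offset keeps merged-region ids distinct from structure ids
        rows.append(MetricRow(100 + rid, *tuple(row.__dict__.values())[1:]))

    df = pd.DataFrame([r.__dict__ for r in rows])
    core = df.iloc[: len(protocol.structures)]
    ok = core[core.present_gt & core.present_pred]
    n_excluded = len(core) - len(ok)
    macro = {
        "structure_id": -1,
        "name": "macro_mean",
        "dice": ok.dice.mean(),
        "volsim": ok.volsim.mean(),
        "hd_mm": ok.hd_mm.mean(),
        "hd95_mm": ok.hd95_mm.mean(),
        "present_gt": n_excluded == 0,
        "present_pred": n_excluded == 0,
    }
    return pd.concat([df, pd.DataFrame([macro])], ignore_index=True)


@dataclass(frozen=True)
class ICCResult:
    """Two-way single-measurement consistency ICC with a 95% CI."""

    icc: float
    ci95_low: float
    ci95_high: float
    n_subjects: int


def icc_agreement(scan1_volumes, scan2_volumes, alpha: float = 0.05) -> ICCResult:
    """Test-retest ICC of paired per-subject measurements.

    Two-way mixed effects, single measurement, consistency type (often
    written ICC(3,1)): with the two scans as the fixed "raters",

        ICC = (MS_subject - MS_error) / (MS_subject + (k-1) MS_error)

    from the two-way ANOVA mean squares with k = 2 measurements.  The 95%
    confidence interval follows from F-distribution bounds on the ratio
    F = MS_subject / MS_error with (n-1) and (n-1)(k-1) degrees of freedom:
    with F_L = F / F_{1-a/2} and F_U = F * F'_{1-a/2} (quantiles at the
    swapped degree-of-freedom orders), the interval is
    [(F_L - 1) / (F_L + k - 1), (F_U - 1) / (F_U + k - 1)].
    """
    x = np.asarray(scan1_volumes, float)
    y = np.asarray(scan2_volumes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D measurement vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    data = np.stack([x, y], axis=1)  # n subjects x k=2 measurements
    k = 2
    grand = data.mean()
    subj_mean = data.mean(axis=1)
    meas_mean = data.mean(axis=0)
    if np.allclose(subj_mean, subj_mean[0]):
        raise ValueError("zero between-subject variance: ICC undefined")
    ss_subj = k * ((subj_mean - grand) ** 2).sum()
    ss_meas = n * ((meas_mean - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = max(ss_tot - ss_subj - ss_meas, 0.0)  # guard float cancellation
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err == 0 or ms_err < 1e-14 * ms_subj:
        return ICCResult(1.0, 1.0, 1.0, n)
    icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    f_obs = ms_subj / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + (k - 1))
    hi = (f_u - 1) / (f_u + (k - 1))
    return ICCResult(float(icc), float(lo), float(hi), n)


def paired_wilcoxon(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns ``(statistic, p)`` where the statistic is the signed rank sum
    T+ - T- (positive when ``values_a`` tends to exceed ``values_b``), so
    swapping the arguments flips its sign but not the p-value.  Zero
    differences are discarded (Wilcoxon's original treatment); the null
    distribution is exact for n <= 25 pairs and a normal approximation
    beyond.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: test degenerate")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                         method=method)
    return t_plus - t_minus, float(res.pvalue)


def outlier_scan(values_by_class: dict, n_sd: float = 2.5) -> dict:
    """Flag values outside mean +/- ``n_sd`` standard deviations per class.

    Returns a dict mapping each class key to a boolean flag array.  Classes
    with fewer than 3 values, or zero spread, produce no flags.
    """
    flags = {}
    for key, vals in values_by_class.items():
        v = np.asarray(vals, float)
        if v.size < 3:
            flags[key] = np.zeros(v.size, dtype=bool)
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            flags[key] = np.zeros(v.size, dtype=bool)
            continue
        flags[key] = np.abs(v - v.mean()) > n_sd * sd
    return flags
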