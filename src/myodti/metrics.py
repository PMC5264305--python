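"""Per-segment structural metrics of infarct remodeling.

For each transmural LV segment: wall thickness, scar transmurality, the linear
fit (slope, intercept, r^2) of inclination angle against wall depth from the
epicardium, the [1-99]% inclination angle range, handedness ratios (fractions
of left-handed / circumferential / right-handed voxels), mean imbrication
angle, and intervoxel angle incoherency (mean acute angular difference between
6-connected neighbor voxels within the segment, computed separately for the
inclination and imbrication maps).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "scar_transmurality",
    "transmural_profile_fit",
    "inclination_range",
    "handedness_ratios",
    "imbrication_mean",
    "angle_incoherency",
    "incoherency_by_segment",
    "compute_segment_table",
    "MIN_PROFILE_VOXELS",
    "HANDEDNESS_THRESHOLD_DEG",
]

MIN_PROFILE_VOXELS = 4  # minimum voxels across the wall for a reliable profile
HANDEDNESS_THRESHOLD_DEG = 15.0
RANGE_PERCENTILES = (1.0, 99.0)


def scar_transmurality(n_fibrotic: int, n_voxels: int) -> float:
    """Fraction of segment voxels classified as fibrotic on LGE."""
    if n_voxels < 1:
        raise ValueError("empty segment: transmurality undefined")
    if not 0 <= n_fibrotic <= n_voxels:
        raise ValueError("fibrotic count must lie in [0, n_voxels]")
    return n_fibrotic / n_voxels


def transmural_profile_fit(
    inclination_deg: np.ndarray, depth_mm: np.ndarray
) -> tuple[float, float, float]:
    """OLS line of inclination angle vs wall depth from the epicardium.

    Returns (slope deg/mm, intercept deg, r^2). Requires >= 4 voxels spanning
    >= 2 distinct depths. A constant angle profile gives slope 0 and r^2 = 0.
    """
    y = np.asarray(inclination_deg, dtype=float)
    x = np.asarray(depth_mm, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_PROFILE_VOXELS:
        raise ValueError(f"profile fit needs >= {MIN_PROFILE_VOXELS} voxels")
    var_x = np.var(x)
    if var_x == 0:
        raise ValueError("all depths equal: profile fit undefined")
    slope = float(np.cov(x, y, bias=True)[0, 1] / var_x)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return slope, intercept, r2


def inclination_range(inclination_deg: np.ndarray) -> float:
    """[1-99]% range of the inclination distribution (linear-interp percentiles)."""
    v = np.asarray(inclination_deg, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < MIN_PROFILE_VOXELS:
        raise ValueError(f"range needs >= {MIN_PROFILE_VOXELS} values")
    lo, hi = np.percentile(v, RANGE_PERCENTILES, method="linear")
    return float(hi - lo)


def handedness_ratios(inclination_deg: np.ndarray) -> tuple[float, float, float]:
    """Left-handed / circumferential / right-handed voxel fractions.

    LH: alpha < -15 deg; RH: alpha > 15 deg; circumferential: the rest
    (boundary values +/-15 are counted circumferential). The three fractions
    sum to 1.
    """
    v = np.asarray(inclination_deg, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("no valid voxels")
    lh = float(np.mean(v < -HANDEDNESS_THRESHOLD_DEG))
    rh = float(np.mean(v > HANDEDNESS_THRESHOLD_DEG))
    return lh, 1.0 - lh - rh, rh


def imbrication_mean(imbrication_deg: np.ndarray) -> float:
    """Arithmetic mean of signed imbrication angles within a segment."""
    v = np.asarray(imbrication_deg, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("no valid voxels")
    return float(v.mean())


def _acute_diff(a: np.ndarray, b: np.ndarray, period: float = 180.0) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, period - d)


def angle_incoherency(angle_deg: np.ndarray, region_mask: np.ndarray) -> float:
    """Mean acute angular difference over 6-connected in-region voxel pairs.

    Angles are treated as axial (period 180 deg): the pair difference is
    min(|d|, 180 - |d|). NaN angles are excluded; raises if the region has no
    neighboring valid pair.
    """
    angle = np.asarray(angle_deg, dtype=float)
    region = np.asarray(region_mask, dtype=bool) & np.isfinite(angle)
    total, count = 0.0, 0
    for axis in range(angle.ndim):
        a = np.moveaxis(angle, axis, 0)
        m = np.moveaxis(region, axis, 0)
        pair = m[:-1] & m[1:]
        if pair.any():
            total += _acute_diff(a[:-1][pair], a[1:][pair]).sum()
            count += int(pair.sum())
    if count == 0:
        raise ValueError("no neighboring in-region voxel pairs: incoherency undefined")
    return total / count


def incoherency_by_segment(angle_deg: np.ndarray, segment_id: np.ndarray) -> dict[int, float]:
    """Vectorized per-segment incoherency over a whole label volume."""
    angle = np.asarray(angle_deg, dtype=float)
    seg = np.asarray(segment_id)
    valid = (seg >= 0) & np.isfinite(angle)
    n = int(seg.max()) + 1 if valid.any() else 0
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for axis in range(angle.ndim):
        a = np.moveaxis(angle, axis, 0)
        s = np.moveaxis(seg, axis, 0)
        v = np.moveaxis(valid, axis, 0)
        pair = v[:-1] & v[1:] & (s[:-1] == s[1:])
        if not pair.any():
            continue
        ids = s[:-1][pair]
        d = _acute_diff(a[:-1][pair], a[1:][pair])
        np.add.at(sums, ids, d)
        np.add.at(counts, ids, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return {int(i): float(means[i]) for i in range(n) if counts[i] > 0}


_METRIC_COLUMNS = [
    "wall_thickness_mm",
    "scar_transmurality",
    "slope_deg_per_mm",
    "intercept_deg",
    "r2",
    "inclination_range_deg",
    "lh_ratio",
    "circ_ratio",
    "rh_ratio",
    "imbrication_mean_deg",
    "inclination_incoherency_deg",
    "imbrication_incoherency_deg",
    "n_voxels_used",
]


def compute_segment_table(
    records: pd.DataFrame,
    labels,
    angle_maps,
    depth,
    thickness: pd.DataFrame,
    min_thickness_mm: float = 2.0,
) -> pd.DataFrame:
    """All structural metrics for every segment; excluded segments keep NaN metrics.

    ``records`` comes from :func:`myodti.segments.classify_segments`, ``labels``
    is the :class:`~myodti.segments.SegmentLabelVolume`, ``angle_maps`` a
    :class:`~myodti.frame.AngleMaps`, ``depth`` a
    :class:`~myodti.frame.DepthField`, and ``thickness`` the table from
    :func:`myodti.segments.segment_wall_thickness`. A segment is excluded when
    its wall is thinner than ``min_thickness_mm`` or it has fewer than 4 valid
    voxels.
    """
    seg = labels.segment_id
    valid = angle_maps.defined & (seg >= 0)
    seg_flat = seg[valid]
    incl = angle_maps.inclination_deg[valid]
    imb = angle_maps.imbrication_deg[valid]
    dmm = depth.depth_mm[valid]

    order = np.argsort(seg_flat, kind="stable")
    seg_sorted = seg_flat[order]
    bounds = np.searchsorted(seg_sorted, np.unique(seg_sorted))
    groups = {
        int(sid): slice(a, b)
        for sid, a, b in zip(
            np.unique(seg_sorted), bounds, np.append(bounds[1:], seg_sorted.size)
        )
    }
    incl_s, imb_s, dmm_s = incl[order], imb[order], dmm[order]

    inc_inco = incoherency_by_segment(angle_maps.inclination_deg, seg)
    imb_inco = incoherency_by_segment(angle_maps.imbrication_deg, seg)
    thick = thickness.set_index("segment_id")

    out = records.copy()
    for col in _METRIC_COLUMNS:
        out[col] = np.nan
    out["excluded"] = False

    for idx, row in out.iterrows():
        sid = int(row["segment_id"])
        t = thick["thickness_mm"].get(sid, np.nan)
        out.at[idx, "wall_thickness_mm"] = t
        out.at[idx, "scar_transmurality"] = scar_transmurality(
            int(row["n_fibrotic_voxels"]), int(row["n_voxels"])
        )
        sl = groups.get(sid)
        n_used = 0 if sl is None else sl.stop - sl.start
        out.at[idx, "n_voxels_used"] = n_used
        if not np.isfinite(t) or t < min_thickness_mm or n_used < MIN_PROFILE_VOXELS:
            out.at[idx, "excluded"] = True
            continue
        a, d = incl_s[sl], dmm_s[sl]
        try:
            slope, intercept, r2 = transmural_profile_fit(a, d)
        except ValueError:
            out.at[idx, "excluded"] = True
            continue
        out.at[idx, "slope_deg_per_mm"] = slope
        out.at[idx, "intercept_deg"] = intercept
        out.at[idx, "r2"] = r2
        out.at[idx, "inclination_range_deg"] = inclination_range(a)
        lh, circ, rh = handedness_ratios(a)
        out.at[idx, "lh_ratio"] = lh
        out.at[idx, "circ_ratio"] = circ
        out.at[idx, "rh_ratio"] = rh
        out.at[idx, "imbrication_mean_deg"] = imbrication_mean(imb_s[sl])
        out.at[idx, "inclination_incoherency_deg"] = inc_inco.get(sid, np.nan)
        out.at[idx, "imbrication_incoherency_deg"] = imb_inco.get(sid, np.nan)
    out.loc[out["excluded"], "status"] = "excluded"
    return out
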