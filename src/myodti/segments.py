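"""Fibrosis segmentation and polar partition of the LV wall into transmural segments.

Fibrosis is segmented from the LGE channel by two-class Otsu thresholding over
wall voxels followed by a deterministic morphological refinement. The wall is
partitioned, slab by short-axis slab, into 36 angular segments of 10 degrees
around the blood-pool centroid; segments containing fibrotic voxels are labeled
infarcted, and segments of control hearts within a configurable anteroseptal
span are labeled control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentLabelVolume",
    "otsu_fibrosis_mask",
    "refine_mask",
    "partition_lv_segments",
    "classify_segments",
    "segment_wall_thickness",
    "N_ANGULAR_BINS",
    "MIN_THICKNESS_MM",
]

N_ANGULAR_BINS = 36  # 10-degree bins
MIN_THICKNESS_MM = 2.0  # segments thinner than this are excluded


@dataclass
class SegmentLabelVolume:
    """Per-voxel transmural segment labels.

    ``segment_id = slab_index * 36 + angular_bin``; -1 marks wall voxels in
    excluded slabs (and non-wall voxels). ``origins_mm`` maps each included slab
    to its polar origin (blood-pool centroid, world mm) and z-slice range.
    """

    segment_id: np.ndarray  # int array, -1 outside / excluded
    slab_index: np.ndarray
    angular_bin: np.ndarray
    excluded: np.ndarray  # wall voxels not assigned to any segment
    origins_mm: dict  # slab -> (cx, cy, z_lo_idx, z_hi_idx)
    slab_thickness_mm: float
    n_angular: int = N_ANGULAR_BINS


def otsu_fibrosis_mask(lge: np.ndarray, lv_mask: np.ndarray) -> np.ndarray:
    """Two-class Otsu threshold over wall voxels; above-threshold voxels are fibrotic.

    A constant-intensity wall has no threshold: an empty mask is returned with
    a warning.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not lv_mask.any():
        raise ValueError("lv_mask is empty")
    values = np.asarray(lge, dtype=float)[lv_mask]
    if np.ptp(values) == 0:
        warnings.warn("constant wall intensity: no Otsu threshold, empty fibrosis mask")
        return np.zeros_like(lv_mask)
    thr = threshold_otsu(values)
    return (np.asarray(lge, dtype=float) > thr) & lv_mask


def refine_mask(mask: np.ndarray, min_component_voxels: int = 10) -> np.ndarray:
    """Deterministic morphological refinement of a binary fibrosis mask.

    Closing then opening with a 1-voxel (6-connected) structuring element,
    followed by removal of connected components smaller than
    ``min_component_voxels``.
    """
    mask = np.asarray(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)
    out = ndimage.binary_closing(mask, structure=struct)
    out = ndimage.binary_opening(out, structure=struct)
    labels, n = ndimage.label(out, structure=struct)
    if n:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_component_voxels)
        out[np.isin(labels, small[small > 0])] = False
    return out


def partition_lv_segments(
    lv_mask: np.ndarray,
    blood_mask: np.ndarray,
    voxel_size_mm=(1.0, 1.0, 1.0),
    slab_thickness_mm: float = 1.2,
    n_angular: int = N_ANGULAR_BINS,
    apex_fraction: float = 0.10,
    apex_end: str = "low",
) -> SegmentLabelVolume:
    """Partition the wall into per-slab polar segments around the blood centroid.

    Short-axis slabs of ``slab_thickness_mm`` are formed along z; in each slab
    the polar origin is the blood-pool centroid and the wall is divided into
    ``n_angular`` equal angular bins (theta measured counterclockwise from +x).
    Slabs without a blood pool and slabs within the apical ``apex_fraction`` of
    the wall's long-axis extent are excluded.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    blood_mask = np.asarray(blood_mask, dtype=bool)
    if not blood_mask.any():
        raise ValueError("no blood pool found: cannot define polar origins")
    if not lv_mask.any():
        raise ValueError("wall mask is empty")
    vx, vy, vz = (float(v) for v in voxel_size_mm)

    wall_z = np.flatnonzero(lv_mask.any(axis=(0, 1)))
    z_lo, z_hi = wall_z.min(), wall_z.max()
    slices_per_slab = max(int(round(slab_thickness_mm / vz)), 1)

    extent = (z_hi - z_lo + 1) * vz
    apex_mm = apex_fraction * extent
    n_apex_slabs = int(np.ceil(apex_mm / slab_thickness_mm))

    shape = lv_mask.shape
    segment_id = np.full(shape, -1, dtype=np.int32)
    slab_index = np.full(shape, -1, dtype=np.int32)
    angular_bin = np.full(shape, -1, dtype=np.int32)
    origins: dict[int, tuple] = {}

    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    n_slabs = int(np.ceil((z_hi - z_lo + 1) / slices_per_slab))
    for slab in range(n_slabs):
        a = z_lo + slab * slices_per_slab
        b = min(a + slices_per_slab, z_hi + 1)
        if apex_end == "low":
            is_apical = slab < n_apex_slabs
        else:
            is_apical = slab >= n_slabs - n_apex_slabs
        blood_slab = blood_mask[:, :, a:b]
        wall_slab = lv_mask[:, :, a:b]
        if is_apical or not blood_slab.any() or not wall_slab.any():
            continue
        bi, bj, _ = np.nonzero(blood_slab)
        cx, cy = bi.mean() * vx, bj.mean() * vy
        origins[slab] = (cx, cy, a, b)

        theta = np.degrees(np.arctan2(jj * vy - cy, ii * vx - cx)) % 360
        bins = np.floor(theta / (360.0 / n_angular)).astype(np.int32)
        bins = np.clip(bins, 0, n_angular - 1)
        for k in range(a, b):
            w = lv_mask[:, :, k]
            segment_id[:, :, k][w] = slab * n_angular + bins[w]
            slab_index[:, :, k][w] = slab
            angular_bin[:, :, k][w] = bins[w]

    excluded = lv_mask & (segment_id < 0)
    return SegmentLabelVolume(
        segment_id=segment_id,
        slab_index=slab_index,
        angular_bin=angular_bin,
        excluded=excluded,
        origins_mm=origins,
        slab_thickness_mm=slab_thickness_mm,
        n_angular=n_angular,
    )


def _bin_center_deg(angular_bin: int, n_angular: int) -> float:
    return (angular_bin + 0.5) * 360.0 / n_angular


def classify_segments(
    labels: SegmentLabelVolume,
    fibrosis_mask: np.ndarray | None,
    heart_type: str = "infarcted",
    control_span_deg: tuple[float, float] = (0.0, 180.0),
    heart_id: str | int = 0,
) -> pd.DataFrame:
    """One record per segment with voxel counts and infarcted/control/other status.

    Infarcted hearts: a segment is infarcted iff it contains >= 1 fibrotic voxel.
    Control hearts: segments whose angular-bin center lies within the configured
    anteroseptal span are control segments.
    """
    lo, hi = control_span_deg
    if not (0 <= lo <= 360 and 0 <= hi <= 360):
        raise ValueError("control span must lie within [0, 360] degrees")
    if heart_type not in ("infarcted", "control"):
        raise ValueError("heart_type must be 'infarcted' or 'control'")

    seg = labels.segment_id
    in_seg = seg >= 0
    ids, counts = np.unique(seg[in_seg], return_counts=True)
    if fibrosis_mask is not None:
        fib = np.zeros_like(counts)
        fib_ids, fib_counts = np.unique(
            seg[in_seg & np.asarray(fibrosis_mask, dtype=bool)], return_counts=True
        )
        fib = np.zeros(ids.max() + 1, dtype=int)
        fib[fib_ids] = fib_counts
        n_fibrotic = fib[ids]
    else:
        n_fibrotic = np.zeros_like(counts)

    slab = ids // labels.n_angular
    abin = ids % labels.n_angular
    status = np.full(ids.shape, "other", dtype=object)
    if heart_type == "infarcted":
        status[n_fibrotic >= 1] = "infarcted"
    else:
        centers = (abin + 0.5) * 360.0 / labels.n_angular
        if lo <= hi:
            in_span = (centers >= lo) & (centers <= hi)
        else:
            in_span = (centers >= lo) | (centers <= hi)
        status[in_span] = "control"

    return pd.DataFrame(
        {
            "heart_id": heart_id,
            "segment_id": ids,
            "slice_index": slab,
            "angular_bin": abin,
            "status": status,
            "n_voxels": counts,
            "n_fibrotic_voxels": n_fibrotic,
        }
    )


def segment_wall_thickness(
    labels: SegmentLabelVolume,
    lv_mask: np.ndarray,
    voxel_size_mm=(1.0, 1.0, 1.0),
    ray_step_deg: float = 1.0,
    radial_step_factor: float = 0.25,
    min_thickness_mm: float = MIN_THICKNESS_MM,
) -> pd.DataFrame:
    """Mean radial wall-intersection length (mm) per segment, by ray casting.

    For each slab, rays are cast from the polar origin at ``ray_step_deg``
    steps through the slab's wall-mask union; a ray's thickness is its total
    in-wall radial intersection length. Segment thickness is the mean over the
    rays within its bin; rays that miss the wall are skipped, and segments
    thinner than ``min_thickness_mm`` are flagged excluded.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    vx, vy, _ = (float(v) for v in voxel_size_mm)
    nx, ny = lv_mask.shape[:2]
    r_max = float(np.hypot(nx * vx, ny * vy)) / 2
    dr = radial_step_factor * min(vx, vy)
    radii = np.arange(dr / 2, r_max, dr)

    rows = []
    thetas = np.arange(0.0, 360.0, ray_step_deg)
    bin_width = 360.0 / labels.n_angular
    for slab, (cx, cy, a, b) in labels.origins_mm.items():
        wall2d = lv_mask[:, :, a:b].any(axis=2)
        # sample all rays at once: (n_theta, n_r) points
        tx = np.cos(np.deg2rad(thetas))[:, None] * radii[None, :] + cx
        ty = np.sin(np.deg2rad(thetas))[:, None] * radii[None, :] + cy
        xi = np.rint(tx / vx).astype(int)
        yi = np.rint(ty / vy).astype(int)
        inside = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny)
        hit = np.zeros(xi.shape, dtype=bool)
        hit[inside] = wall2d[xi[inside], yi[inside]]
        ray_thickness = hit.sum(axis=1) * dr  # per-ray intersection length

        ray_bin = np.floor(thetas / bin_width).astype(int) % labels.n_angular
        for abin in range(labels.n_angular):
            vals = ray_thickness[(ray_bin == abin)]
            vals = vals[vals > 0]
            if vals.size == 0:
                thickness = np.nan
            else:
                thickness = float(vals.mean())
            rows.append(
                {
                    "segment_id": slab * labels.n_angular + abin,
                    "thickness_mm": thickness,
                    "thin_excluded": bool(np.isnan(thickness) or thickness < min_thickness_mm),
                }
            )
    return pd.DataFrame(rows)
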