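"""End-to-end orchestration: phantom -> tensors -> angles -> segments -> statistics.

``analyze_heart`` runs the per-heart chain on in-memory volumes;
``run_pipeline`` drives a single phantom heart from a config and writes all
NIfTI/CSV artifacts plus a JSON run manifest; ``run_cohort_study`` builds an
infarcted-vs-control phantom cohort and emits the summary tables (diffusion
scalars by tissue class, segment metrics by group, correlations, Monte-Carlo
eigenvector uncertainty).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import scipy
import yaml
from scipy import ndimage

from . import __version__, io
from .dti import DWIVolume, SnrReport, TensorField, fit_tensor, measure_snr
from .frame import AngleMaps, DepthField, FrameField, angle_maps, compute_local_frame, wall_depth
from .metrics import compute_segment_table
from .phantom import PhantomBundle, PhantomParams, generate_phantom
from .segments import (
    SegmentLabelVolume,
    classify_segments,
    otsu_fibrosis_mask,
    partition_lv_segments,
    refine_mask,
    segment_wall_thickness,
)
from .stats import mc_eigenvector_uncertainty, pearson_r, summarize_groups

__all__ = [
    "AnalysisOptions",
    "PipelineConfig",
    "HeartAnalysis",
    "background_mask_from_tissue",
    "analyze_heart",
    "run_pipeline",
    "run_cohort_study",
]

log = logging.getLogger("myodti")


@dataclass(frozen=True)
class AnalysisOptions:
    heart_type: str = "infarcted"
    control_span_deg: tuple[float, float] = (0.0, 180.0)
    slab_thickness_mm: float = 1.2
    min_thickness_mm: float = 2.0
    use_lge: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pp = raw.get("phantom", {})
        for key in ("voxel_size_mm", "grid_shape", "scar_sector_deg", "scar_transmural_span"):
            if key in pp and pp[key] is not None:
                pp[key] = tuple(pp[key])
        an = raw.get("analysis", {})
        if "control_span_deg" in an:
            an["control_span_deg"] = tuple(an["control_span_deg"])
        return cls(phantom=PhantomParams(**pp), analysis=AnalysisOptions(**an))

    def to_dict(self) -> dict:
        return {"phantom": asdict(self.phantom), "analysis": asdict(self.analysis)}


@dataclass
class HeartAnalysis:
    heart_id: str | int
    tensors: TensorField
    frame: FrameField
    depth: DepthField
    angles: AngleMaps
    fibrosis_mask: np.ndarray | None
    labels: SegmentLabelVolume
    segment_table: pd.DataFrame
    snr: SnrReport | None


def background_mask_from_tissue(
    tissue: np.ndarray, margin_voxels: int = 6
) -> np.ndarray:
    """Signal-free background ROI: everything farther than ``margin_voxels`` from tissue."""
    dil = ndimage.binary_dilation(
        np.asarray(tissue, dtype=bool), iterations=margin_voxels
    )
    return ~dil


def analyze_heart(
    dwi: DWIVolume,
    lv_mask: np.ndarray,
    blood_mask: np.ndarray,
    lge: np.ndarray | None = None,
    options: AnalysisOptions | None = None,
    heart_id: str | int = 0,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> HeartAnalysis:
    """Per-heart analysis chain: tensor fit, angle maps, segmentation, metrics."""
    options = options or AnalysisOptions()
    lv_mask = np.asarray(lv_mask, dtype=bool)
    blood_mask = np.asarray(blood_mask, dtype=bool)

    log.info("heart %s: fitting tensors", heart_id)
    if dwi.mask is None:
        dwi = replace(dwi, mask=lv_mask)
    tensors = fit_tensor(dwi)

    b0 = dwi.signals[..., dwi.scheme.b0_index].mean(axis=-1)
    background = background_mask_from_tissue(lv_mask | blood_mask)
    snr = None
    if background.any():
        try:
            snr = measure_snr(b0, lv_mask, background)
        except ValueError:
            snr = None  # e.g. noiseless simulation: zero-variance background

    log.info("heart %s: local frame and angle maps", heart_id)
    frm = compute_local_frame(blood_mask, lv_mask, voxel_size_mm=voxel_size_mm)
    depth = wall_depth(lv_mask, blood_mask, voxel_size_mm=voxel_size_mm)
    angles = angle_maps(tensors.v1, frm, valid=tensors.valid_mask)

    fibrosis = None
    if lge is not None and options.use_lge and options.heart_type == "infarcted":
        # control hearts carry no enhanced tissue: a two-class threshold on their
        # unimodal wall histogram would only split noise
        log.info("heart %s: fibrosis segmentation", heart_id)
        fibrosis = refine_mask(otsu_fibrosis_mask(lge, lv_mask))

    log.info("heart %s: polar segmentation and metrics", heart_id)
    labels = partition_lv_segments(
        lv_mask,
        blood_mask,
        voxel_size_mm=voxel_size_mm,
        slab_thickness_mm=options.slab_thickness_mm,
    )
    records = classify_segments(
        labels,
        fibrosis,
        heart_type=options.heart_type,
        control_span_deg=options.control_span_deg,
        heart_id=heart_id,
    )
    thickness = segment_wall_thickness(
        labels, lv_mask, voxel_size_mm=voxel_size_mm, min_thickness_mm=options.min_thickness_mm
    )
    table = compute_segment_table(
        records, labels, angles, depth, thickness, min_thickness_mm=options.min_thickness_mm
    )
    return HeartAnalysis(
        heart_id=heart_id,
        tensors=tensors,
        frame=frm,
        depth=depth,
        angles=angles,
        fibrosis_mask=fibrosis,
        labels=labels,
        segment_table=table,
        snr=snr,
    )


def analyze_phantom(
    bundle: PhantomBundle, options: AnalysisOptions | None = None, heart_id: str | int = 0
) -> HeartAnalysis:
    """Run :func:`analyze_heart` on a generated phantom bundle."""
    opts = options or AnalysisOptions(
        heart_type="infarcted" if bundle.params.scar_sector_deg is not None else "control"
    )
    return analyze_heart(
        bundle.dwi,
        bundle.lv_mask,
        bundle.blood_mask,
        lge=bundle.lge if opts.use_lge else None,
        options=opts,
        heart_id=heart_id,
        voxel_size_mm=bundle.params.voxel_size_mm,
    )


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(path: str, config: PipelineConfig, seed: int, extras: dict) -> None:
    manifest = {
        "myodti_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "multiple_testing_correction": "none",
        **extras,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig, seed: int, out_dir: str) -> str:
    """Single-heart phantom pipeline; writes volumes, metric table, and manifest.

    Deterministic given (config, seed): two runs produce byte-identical CSVs.
    """
    os.makedirs(out_dir, exist_ok=True)
    params = replace(config.phantom, seed=seed)
    log.info("generating phantom (seed=%d)", seed)
    bundle = generate_phantom(params)
    result = analyze_phantom(bundle, config.analysis, heart_id=0)

    aff = bundle.affine
    io.save_nifti(bundle.lv_mask, aff, os.path.join(out_dir, "lv_mask.nii.gz"))
    io.save_nifti(bundle.blood_mask, aff, os.path.join(out_dir, "blood_mask.nii.gz"))
    io.save_nifti(bundle.scar_mask, aff, os.path.join(out_dir, "scar_mask_true.nii.gz"))
    io.save_nifti(bundle.dwi.signals, aff, os.path.join(out_dir, "dwi.nii.gz"))
    io.write_bvals_bvecs(
        bundle.dwi.scheme.b_values,
        bundle.dwi.scheme.directions,
        os.path.join(out_dir, "dwi.bval"),
        os.path.join(out_dir, "dwi.bvec"),
    )
    io.save_nifti(bundle.lge, aff, os.path.join(out_dir, "lge.nii.gz"))
    io.save_nifti(result.tensors.md, aff, os.path.join(out_dir, "md.nii.gz"))
    io.save_nifti(np.nan_to_num(result.tensors.fa), aff, os.path.join(out_dir, "fa.nii.gz"))
    io.save_nifti(result.tensors.v1, aff, os.path.join(out_dir, "v1.nii.gz"))
    io.save_nifti(
        np.nan_to_num(result.angles.inclination_deg),
        aff,
        os.path.join(out_dir, "inclination.nii.gz"),
    )
    io.save_nifti(
        np.nan_to_num(result.angles.imbrication_deg),
        aff,
        os.path.join(out_dir, "imbrication.nii.gz"),
    )
    if result.fibrosis_mask is not None:
        io.save_nifti(result.fibrosis_mask, aff, os.path.join(out_dir, "fibrosis_mask.nii.gz"))
    io.save_nifti(result.labels.segment_id, aff, os.path.join(out_dir, "segments.nii.gz"))
    result.segment_table.to_csv(os.path.join(out_dir, "segment_metrics.csv"), index=False)

    _write_manifest(
        os.path.join(out_dir, "manifest.json"),
        config,
        seed,
        {"n_segments": int(len(result.segment_table)), "snr": result.snr.snr if result.snr else None},
    )
    return out_dir


def run_cohort_study(
    config: PipelineConfig | None = None,
    n_infarcted: int = 8,
    n_control: int = 4,
    seed: int = 0,
    out_dir: str | None = None,
    mc_reps: int = 1000,
    mc_snr_grid: tuple[float, ...] = (30.0, 60.0, 120.0),
) -> dict:
    """Infarcted-vs-control phantom cohort with full summary statistics.

    Returns a dict with the pooled segment table, per-heart and per-segment
    group comparisons, pooled voxel diffusion scalars by tissue class,
    correlation table, and Monte-Carlo uncertainty table; optionally writes
    them as CSV plus a manifest.
    """
    config = config or PipelineConfig()
    base = config.phantom
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_infarcted + n_control)]

    tables = []
    voxel_rows = []
    for h in range(n_infarcted + n_control):
        infarcted = h < n_infarcted
        params = base if infarcted else base.control()
        params = replace(params, seed=child_seeds[h])
        opts = replace(config.analysis, heart_type="infarcted" if infarcted else "control")
        bundle = generate_phantom(params)
        result = analyze_phantom(bundle, opts, heart_id=h)
        tables.append(result.segment_table)

        # pooled voxel scalars by tissue class (measured fibrosis mask when present)
        valid = result.tensors.valid_mask
        md, fa = result.tensors.md, result.tensors.fa
        ev = result.tensors.eigenvalues
        if infarcted and result.fibrosis_mask is not None:
            classes = {
                "fibrotic": valid & result.fibrosis_mask,
                "non_fibrotic": valid & bundle.lv_mask & ~result.fibrosis_mask,
            }
        else:
            classes = {"normal": valid & bundle.lv_mask}
        for name, m in classes.items():
            if m.any():
                voxel_rows.append(
                    pd.DataFrame(
                        {
                            "heart_id": h,
                            "tissue": name,
                            "md": md[m],
                            "fa": fa[m],
                            "e1": ev[m][:, 0],
                            "e2": ev[m][:, 1],
                            "e3": ev[m][:, 2],
                        }
                    )
                )
        log.info(
            "cohort heart %d/%d (%s): %d segments",
            h + 1,
            n_infarcted + n_control,
            "infarcted" if infarcted else "control",
            len(result.segment_table),
        )

    segment_table = pd.concat(tables, ignore_index=True)
    voxel_table = pd.concat(voxel_rows, ignore_index=True)

    scalars = (
        voxel_table.groupby("tissue")[["md", "fa", "e1", "e2", "e3"]]
        .agg(["mean", "std"])
        .round(10)
    )
    scalars.columns = ["_".join(c) for c in scalars.columns]
    scalars = scalars.reset_index()

    group_per_heart = summarize_groups(segment_table, mode="per_heart")
    group_per_segment = summarize_groups(segment_table, mode="per_segment")

    # associations across all analyzable segments of the infarcted hearts:
    # the thinned (infarcted) and normal-thickness (remote) segments together
    # span the thickness range that drives the slope association
    inf_hearts = segment_table["heart_id"].isin(
        segment_table.loc[segment_table["status"] == "infarcted", "heart_id"].unique()
    )
    inf = segment_table[inf_hearts & ~segment_table["excluded"]].dropna(
        subset=["slope_deg_per_mm", "wall_thickness_mm", "scar_transmurality"]
    )
    corr_rows = []
    if len(inf) >= 3:
        corr_rows = [
            {"pair": "slope_vs_transmurality", "r": pearson_r(inf["slope_deg_per_mm"], inf["scar_transmurality"])},
            {"pair": "slope_vs_inverse_thickness", "r": pearson_r(inf["slope_deg_per_mm"], 1.0 / inf["wall_thickness_mm"])},
            {"pair": "slope_vs_thickness", "r": pearson_r(inf["slope_deg_per_mm"], inf["wall_thickness_mm"])},
            {"pair": "range_vs_transmurality", "r": pearson_r(inf["inclination_range_deg"], inf["scar_transmurality"])},
        ]
    correlations = pd.DataFrame(corr_rows)

    scheme = None
    unc_rows = []
    if mc_reps:
        from .phantom import make_gradient_scheme

        scheme = make_gradient_scheme(base.n_directions, base.b_value, seed=seed)
        for snr in mc_snr_grid:
            for fa_val, md_val, label in (
                (base.fa_fibrotic, base.md_fibrotic, "fibrotic"),
                (base.fa_normal, base.md_normal, "normal"),
            ):
                pt = mc_eigenvector_uncertainty(
                    fa_val, md_val, snr, scheme, n_reps=mc_reps, seed=seed
                )
                unc_rows.append({"tissue": label, **pt.__dict__})
    uncertainty = pd.DataFrame(unc_rows)

    results = {
        "segment_table": segment_table,
        "voxel_scalars": scalars,
        "group_per_heart": group_per_heart,
        "group_per_segment": group_per_segment,
        "correlations": correlations,
        "uncertainty": uncertainty,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        segment_table.to_csv(os.path.join(out_dir, "segments.csv"), index=False)
        scalars.to_csv(os.path.join(out_dir, "table1.csv"), index=False)
        pd.concat([group_per_heart, group_per_segment], ignore_index=True).to_csv(
            os.path.join(out_dir, "table2.csv"), index=False
        )
        correlations.to_csv(os.path.join(out_dir, "correlations.csv"), index=False)
        uncertainty.to_csv(os.path.join(out_dir, "uncertainty.csv"), index=False)
        _write_manifest(
            os.path.join(out_dir, "manifest.json"),
            config,
            seed,
            {"n_infarcted": n_infarcted, "n_control": n_control},
        )
    return results
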