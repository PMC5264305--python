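# myodti

Quantification of chronic myocardial-infarct microstructure from ex-vivo
cardiac diffusion tensor imaging (DTI) and late gadolinium enhancement (LGE)
volumes — for researchers studying post-infarction fiber remodeling in large
animal and human hearts, and for anyone who needs a tested, synthetic-ground-
truth implementation of the standard analysis chain.

## What it computes

After myocardial infarction the left-ventricular (LV) wall thins and scar
collagen replaces myocytes, but the primary diffusion eigenvector — the local
fiber/collagen orientation — largely keeps the healthy transmural pattern.
The package quantifies that remodeling:

- **Diffusion tensors** are fitted voxelwise by log-linear ordinary least
  squares on the Stejskal–Tanner model `S_i = S0 exp(−b gᵢᵀ D gᵢ)`, with
  eigensystem, mean diffusivity `MD = (λ₁+λ₂+λ₃)/3` and fractional anisotropy
  `FA = √(3/2)·‖λ−λ̄‖/‖λ‖`; tensors can be reoriented under a supplied affine
  (finite-strain rule `D′ = R D Rᵀ`).
- **Fiber angles** are measured in a local frame tangent to the endocardial
  surface: `n` the endocardial normal (pointing epicardially), `t = z × n` the
  circumferential direction, `f = n × t`. The *inclination* (helix) angle is
  the angle between the eigenvector's tangent-plane projection and `t`
  (negative = left-handed, epicardial-type); the *imbrication* (transverse)
  angle is its out-of-plane tilt in the `(t, n)` plane.
- **Fibrosis** is segmented from the LGE channel by two-class Otsu
  thresholding over wall voxels plus a deterministic morphological refinement.
- **Polar segmentation** partitions each 1.2-mm short-axis slab into 36
  transmural segments of 10° around the blood-pool centroid.
- **Per-segment metrics**: wall thickness (ray cast), scar transmurality,
  slope/intercept/r² of the inclination-vs-depth regression, the [1–99]%
  inclination angle range, left-handed/circumferential/right-handed voxel
  ratios (±15° boundaries), mean imbrication angle, and intervoxel
  *incoherency* (mean acute angular difference over 6-connected neighbor
  pairs).
- **Group statistics**: Wilcoxon rank-sum tests (exact permutation enumeration
  for small samples, tie-corrected normal approximation otherwise), Pearson
  correlations, percent changes, and a Monte-Carlo analysis of primary
  eigenvector uncertainty as a function of FA and SNR.

Because no real acquisitions ship with the package, a first-class synthetic
phantom module generates cylindrical-annulus LV geometries with a linear
epi→endo inclination rotation (−60° → +52.5°), an optionally thinned infarct
sector with fibrotic tissue properties (MD 9.08 vs 6.33 ×10⁻⁴ mm²/s, FA 0.24
vs 0.37), a 15-direction b = 800 s/mm² acquisition with Rician noise at
SNR 120, and an intensity-enhanced LGE channel — all with exact ground truth
for validation.

## Worked example

```python
import numpy as np
from myodti.phantom import PhantomParams, generate_phantom
from myodti.pipeline import analyze_phantom

params = PhantomParams(grid_shape=(80, 80, 32), seed=42)  # infarcted heart, SNR 120
bundle = generate_phantom(params)
result = analyze_phantom(bundle)

tab = result.segment_table
inf = tab[(tab.status == "infarcted") & ~tab.excluded]
rem = tab[(tab.status == "other") & ~tab.excluded]
print(f"measured b0 SNR: {result.snr.snr:.1f}")
print(f"infarcted segments (n={len(inf)}): wall {inf.wall_thickness_mm.mean():.2f} mm, "
      f"slope {inf.slope_deg_per_mm.mean():.1f} deg/mm, LH ratio {inf.lh_ratio.mean():.2f}, "
      f"scar transmurality {inf.scar_transmurality.mean():.2f}")
print(f"remote segments    (n={len(rem)}): wall {rem.wall_thickness_mm.mean():.2f} mm, "
      f"slope {rem.slope_deg_per_mm.mean():.1f} deg/mm, LH ratio {rem.lh_ratio.mean():.2f}")
```

prints

```
measured b0 SNR: 119.5
infarcted segments (n=84): wall 5.05 mm, slope 23.2 deg/mm, LH ratio 0.56, scar transmurality 0.42
remote segments    (n=420): wall 7.00 mm, slope 16.9 deg/mm, LH ratio 0.47
```

The thinned infarct keeps its epi-to-endo inclination range but traverses it
over a thinner wall, so the transmural slope rises from ~16 °/mm to ~23 °/mm
while the scar transmurality (fibrotic voxel fraction) is ~0.42; the
left-handed voxel ratio rises in the infarcted segments. Pooled voxel scalars
from the fitted tensors recover the generating tissue values (fibrotic
MD 9.08×10⁻⁴ mm²/s / FA 0.24 vs remote 6.35×10⁻⁴ / 0.37 in this run).

A command-line interface wraps the same chain:

```bash
myodti phantom --out ph/ --seed 3          # write DWI + masks + LGE as NIfTI
myodti fit --dwi ph/dwi.nii.gz --bval ph/dwi.bval --bvec ph/dwi.bvec \
           --mask ph/lv_mask.nii.gz --out maps/
myodti run --seed 3 --out run/             # full single-heart pipeline
myodti cohort --seed 3 --out cohort/       # 8-vs-4 cohort with summary tables
```

## Layout

- `src/myodti/phantom.py` — synthetic LV generator (geometry, ground-truth
  fibers/tensors, gradient schemes, DWI + LGE simulation)
- `src/myodti/dti.py` — tensor fit, eigensystems, MD/FA, reorientation, SNR
- `src/myodti/frame.py` — endocardial frame, wall depth, angle maps
- `src/myodti/segments.py` — Otsu fibrosis segmentation, polar partition,
  wall thickness
- `src/myodti/metrics.py` — per-segment structural metrics
- `src/myodti/stats.py` — rank-sum/Pearson/percent change, MC uncertainty
- `src/myodti/pipeline.py`, `src/myodti/cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
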