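# Methods

This note documents the models, numerical choices, and limitations behind
`myodti`. It is written for a reader who wants to judge what the package's
validation does — and does not — establish about real data.

## Signal model and tensor estimation

Diffusion-weighted signals follow the monoexponential Stejskal–Tanner model
`S_i = S0 exp(−b_i gᵢᵀ D gᵢ)` with a symmetric positive-definite tensor `D`
(mm²/s). Tensors are estimated voxelwise by ordinary least squares on
`ln(S0/S_i)` against the six independent tensor elements through the design
rows `b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz)`. OLS rather than weighted least
squares is the default because at the SNR regime targeted here (≈120 in the
b=0 image) the heteroscedasticity of log-domain noise is negligible; the fit
is exact on noiseless input, which the test suite exploits as a round-trip
oracle. Non-positive signals are clamped to `1e−6·S0` and the voxel flagged in
`valid_mask`; negative fitted eigenvalues are kept but flagged, never clipped,
so quality control can count them. `S0` is the mean of the b=0 volumes.

Reorientation under a supplied affine uses the finite-strain rule: the
rotation factor of the polar decomposition of the affine's linear part is
applied as `D′ = R D Rᵀ`, leaving MD and FA unchanged; resampling is
nearest-neighbor to avoid tensor-interpolation ambiguity. Registration
*estimation* is out of scope — phantom data are registered by construction.

SNR of a magnitude b=0 image is measured as `mean(tissue)/σ` with
`σ = std(background)/√(2−π/2)`, the Rayleigh correction for a signal-free
magnitude background.

## Local frame and fiber angles

Angles are referenced to a frame tangent to the endocardial surface:
`n` (endocardial normal, pointing toward the epicardium), `t = z × n`
(circumferential; `z` the apex→base axis), `f = n × t`. With this sign choice
`f` points apex→base on the free wall, so positive inclination corresponds to
right-handed (endocardial-type) helices and negative to left-handed
(epicardial-type) ones, and positive imbrication means a tilt toward the
epicardium.

The normal field is the normalized gradient of a transmural scalar field,
lightly smoothed (1 voxel Gaussian). Two fields are implemented:

* **harmonic** (default): the solution of Laplace's equation over the wall
  with Dirichlet values 0 in the endocardial region and 1 outside the
  epicardium, computed by damped Jacobi iteration from an EDT-ratio initial
  guess (600 iterations or a 1e−6 max-update tolerance). Elliptic regularity
  makes its gradient smooth; on the cylindrical phantom the worst per-segment
  mean imbrication bias is ≈0.4°.
* **signed_distance**: the gradient of the signed Euclidean distance to the
  endocardial surface. Simpler, but the voxelized surface facets the distance
  field; the resulting in-plane normal errors bias per-segment mean
  imbrication by up to a few degrees. It is retained as an option and for
  comparison.

Angle conventions: the eigenvector is first flipped so its `t`-component is
non-negative (axial data are sign-ambiguous); inclination is
`atan2(e1·f, e1·t)` in [−90°, 90°] with pure-`f` vectors folding to +90°;
imbrication is `atan2(e1·n, e1·t)`, flagged low-confidence when
`|e1·t| < 0.05` (near-longitudinal fibers make the transverse angle
ill-conditioned). Both angles are invariant under `e1 → −e1` and undefined
where the eigenvector is parallel to `n` or the frame itself is undefined
(`n` parallel to `z`).

Wall depth is measured from the epicardium: `depth_mm` is the Euclidean
distance to the epicardial surface less half a voxel (so surface-layer voxels
read ≈0), and `depth_norm = d_epi/(d_epi+d_endo)`. Depth from the epicardium
(not the endocardium) is the regression axis for transmural profiles; the
fitted intercepts are then directly the epicardial angles (≈ −60°).

## Fibrosis segmentation and LV partition

Fibrosis is segmented on the LGE channel by a two-class Otsu threshold
computed over wall voxels only, followed by a deterministic morphological
refinement (1-voxel 6-connected closing then opening, removal of connected
components under 10 voxels). The refinement replaces an interactive level-set
step used in practice; it is reproducible and is validated by
before/after Dice on corrupted phantom masks. Control hearts are not
thresholded: their wall histogram is unimodal and a two-class split would
only partition noise.

Each 1.2-mm short-axis slab is partitioned into 36 angular segments of 10°
around the blood-pool centroid of that slab, with θ measured counterclockwise
from the image +x axis (anatomical labels are a configuration mapping).
Slabs without a blood pool and slabs in the apical 10% of the wall's
long-axis extent are excluded. Segments of infarcted hearts are *infarcted*
iff they contain at least one fibrotic voxel; segments of control hearts
within a configurable 180° anteroseptal span are *control*.

Per-segment wall thickness is the mean over 1°-spaced rays from the slab
origin of the ray's in-wall radial intersection length. Segments thinner than
2 mm, or with fewer than 4 valid voxels, are excluded from angle metrics —
thin walls do not support a reliable transmural profile.

## Segment metrics

For each transmural segment: scar transmurality (fibrotic voxel fraction);
OLS slope, intercept, and r² of inclination vs depth (constant profiles give
slope 0 and r² defined as 0); the [1–99]% inclination range
(linear-interpolation percentiles — stated because percentile conventions
matter at segment-level sample sizes); left-handed (α < −15°),
circumferential, and right-handed (α > 15°) voxel fractions, with the
boundary values ±15° assigned to the circumferential class so the three
fractions always sum to 1; mean signed imbrication; and incoherency — the
mean acute angular difference `min(|Δ|, 180−|Δ|)` over 6-connected
in-segment voxel pairs, computed separately for the inclination and
imbrication maps. The acute-difference-over-neighbor-pairs definition is this
package's own (the measure is conceptually a disarray proxy; competing
definitions exist), and it treats angles as axial data with period 180°.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test: exact permutation
enumeration over all `C(n+m, n)` labelings when `min(n, m) ≤ 8` (the 8-vs-4
per-heart design), midrank-based and therefore tie-safe, and the
tie-corrected normal approximation for larger samples (the two agree within
0.02 at n = m = 7, which the suite checks). Per-heart mode averages each
metric within heart before testing; per-segment mode pools records — with
~10× the sample size it yields smaller p-values for the same effect, which is
a statement about power, not about different biology. No multiple-testing
correction is applied, and that is recorded in the output manifest. Percent
changes are reported relative to the control/normal group and rounded to
integer percent only at presentation.

The Monte-Carlo uncertainty analysis simulates a single-voxel prolate tensor
at a given (FA, MD), adds Rician noise at a given SNR, refits, and records
the angle between fitted and true primary eigenvectors (mean and 95th
percentile over ≥100 repetitions, seeded). At SNR 120 the mean deviation at
FA 0.24 exceeds that at FA 0.37, and deviations fall monotonically with SNR —
the premise for interpreting part, but only part, of the measured infarct
incoherency increase as microstructural.

## The phantom: what it emulates and what it does not

The phantom is a straight cylindrical annulus (default: endo radius 10 mm,
epi radius 17 mm → 7.0 mm wall; 0.5 mm isotropic voxels on a 96×96×80 grid,
≈30 included slabs → ≈1000 segments per heart). The wall and blood pool span
the full grid so distance transforms are free of end-cap artifacts.
Inclination varies linearly with normalized depth from −60° (epi) to +52.5°
(endo), a 112.5° range; imbrication is 0 (an injectable tilt exists for
stress tests). Tensors are prolate (λ₂ = λ₃) with the closed-form eigenvalue
split `δ = MD·FA/√(3−2FA²)`; tissue values are MD 6.33/9.08 ×10⁻⁴ mm²/s and
FA 0.37/0.24 for normal/fibrotic tissue. The acquisition is one b=0 volume
plus 15 directions at b = 800 s/mm² (electrostatic-repulsion hemisphere
scheme, design condition number < 10; a classic octahedral preset for n = 6),
with Rician noise (two Gaussian channels, σ = s0/SNR, SNR 120 by default).
The LGE channel is Gaussian (μ 200 in scar, 100 in wall, σ 10, background 0).

The infarct is a 60° sector thinned by the factor 5.1/7.0 (epicardium pulled
inward, endocardium fixed) whose endocardial-half depth span is fibrotic.
Inside the sector the transmural inclination profile is made convex,
`α(d) = α_epi + range·d^γ` with γ = ln 0.4 / ln 0.51 ≈ 1.36. This is a
deliberate design choice: a thinning-only infarct with a linear profile
preserves the handedness fractions exactly (they are fractions of the depth
distribution), so it cannot produce the left-handed-ratio increase that
coexists with a preserved angle range in remodeled walls. The convex profile
emulates the observed endocardial depression of inclination; γ was fixed once
so the analytic left-handed fraction in the sector is 0.51 against 0.40 for
the linear profile, and it also lowers the fitted intercept and raises the
slope in infarcted segments, in the observed directions.

Known gaps between phantom and reality, hence limits on what green tests
mean: no true fiber disarray (the infarct incoherency increase in the phantom
comes from the steeper transmural gradient and the higher eigenvector noise
at low FA, not from microstructural disorder); no partial-volume or
k-space/Gibbs effects; no eddy-current or susceptibility artifacts; no
fixation shrinkage; cylindrical rather than anatomical geometry (so
curvature- and apex-related frame errors are not exercised); annular voxel
density makes depth sampled with weight ∝ radius, which shifts handedness
fractions slightly from their uniform-depth values (the tests use the
area-weighted closed forms as oracles). Scaled-down grids (80×80×32) are used
for cohort-level runs; per-heart metric means are insensitive to the number
of slabs because segments are statistically identical along the long axis.

## Numerical details worth knowing

- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; cohort hearts draw child seeds from a `SeedSequence`.
  Outputs are bit-for-bit reproducible for a fixed (config, seed).
- Eigenvectors from `eigh` are sign-fixed (first nonzero component positive);
  all angle code is sign-invariant anyway.
- The Otsu threshold is computed by `skimage.filters.threshold_otsu` on wall
  intensities and is cross-checked in the tests against an exhaustive
  between-class-variance scan.
- Gradient directions for n > 6 come from a seeded electrostatic-repulsion
  iteration with antipodal symmetry (300 iterations, decaying step); the
  b=0 row carries a placeholder unit direction.
- Ray casting uses 0.125 mm radial sampling with nearest-voxel lookup; single
  rays against a voxelized boundary are jagged by up to ±0.4 mm, which
  averaging over the 10 rays per 10° bin suppresses.
- The harmonic frame solver costs a few seconds on a 96×96×80 grid; its
  iteration count (600) is sized for walls up to ~15 voxels thick. Thicker
  walls at finer resolution would need more iterations or a multigrid.
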