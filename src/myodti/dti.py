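"""Diffusion-tensor estimation, eigensystems, scalar maps, reorientation, SNR.

Tensors are fitted voxelwise by ordinary least squares on the log-signal
(monoexponential Stejskal-Tanner model), the standard approach for high-SNR
ex-vivo data where log-domain heteroscedasticity is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "GradientScheme",
    "DWIVolume",
    "TensorField",
    "SnrReport",
    "design_matrix",
    "fit_tensor",
    "eigendecompose",
    "mean_diffusivity",
    "fractional_anisotropy",
    "reorient_tensors",
    "measure_snr",
]

# std of a Rayleigh(sigma) variate is sigma * sqrt(2 - pi/2)
_RAYLEIGH_STD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: unit directions and per-volume b-values (s/mm^2).

    Exactly the rows of an FSL bval/bvec pair; b == 0 rows are
    non-diffusion-weighted volumes (their direction is a placeholder unit vector).
    """

    directions: np.ndarray  # (n_volumes, 3)
    b_values: np.ndarray  # (n_volumes,)

    def __post_init__(self):
        g = np.asarray(self.directions, dtype=float)
        b = np.asarray(self.b_values, dtype=float)
        object.__setattr__(self, "directions", g)
        object.__setattr__(self, "b_values", b)
        if g.ndim != 2 or g.shape[1] != 3 or g.shape[0] != b.size:
            raise ValueError("directions must be (n, 3) matching b_values")
        norms = np.linalg.norm(g, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("all gradient directions must be unit vectors")
        nz = b > 0
        if nz.sum() < 6:
            raise ValueError("at least 6 diffusion-weighted directions required")
        if np.linalg.matrix_rank(design_matrix(g[nz], b[nz])) < 6:
            raise ValueError("diffusion directions are collinear (rank-deficient design)")

    def __len__(self) -> int:
        return int(self.b_values.size)

    @property
    def dwi_index(self) -> np.ndarray:
        return np.flatnonzero(self.b_values > 0)

    @property
    def b0_index(self) -> np.ndarray:
        return np.flatnonzero(self.b_values == 0)


@dataclass
class DWIVolume:
    """4D diffusion-weighted dataset: (x, y, z, volume) signals plus geometry."""

    signals: np.ndarray
    scheme: GradientScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4D (x, y, z, volume)")
        if self.signals.shape[3] != len(self.scheme):
            raise ValueError("volume count does not match gradient scheme length")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative (magnitude data)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signals.shape[:3]:
                raise ValueError("mask shape does not match signal grid")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with derived eigensystems and scalars.

    ``eigenvectors[..., i, :]`` is the unit eigenvector of ``eigenvalues[..., i]``;
    eigenvalues are sorted descending (e1 >= e2 >= e3). ``valid_mask`` marks voxels
    whose fit is trustworthy (no clamped signals, no negative eigenvalues).
    """

    tensors: np.ndarray  # (..., 3, 3), mm^2/s
    eigenvalues: np.ndarray  # (..., 3)
    eigenvectors: np.ndarray  # (..., 3, 3)
    mask: np.ndarray  # voxels where a tensor is defined
    valid_mask: np.ndarray  # subset of mask

    @classmethod
    def from_tensors(
        cls, tensors: np.ndarray, mask: np.ndarray, valid_mask: np.ndarray | None = None
    ) -> "TensorField":
        evals, evecs = eigendecompose(tensors)
        mask = np.asarray(mask, dtype=bool)
        if valid_mask is None:
            valid_mask = mask.copy()
        valid_mask = np.asarray(valid_mask, dtype=bool) & mask
        # negative eigenvalues are kept but flagged so QC can count them
        valid_mask = valid_mask & ~(np.min(evals, axis=-1) < 0)
        return cls(tensors, evals, evecs, mask, valid_mask)

    @property
    def v1(self) -> np.ndarray:
        return self.eigenvectors[..., 0, :]

    @property
    def md(self) -> np.ndarray:
        return mean_diffusivity(self.eigenvalues)

    @property
    def fa(self) -> np.ndarray:
        return fractional_anisotropy(self.eigenvalues)


@dataclass(frozen=True)
class SnrReport:
    mean_signal: float
    noise_sigma: float
    snr: float
    roi_labels: tuple[str, str] = ("tissue", "background")


def design_matrix(directions: np.ndarray, b_values: np.ndarray) -> np.ndarray:
    """Rows b*(gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz) for the log-linear fit."""
    g = np.asarray(directions, dtype=float)
    b = np.asarray(b_values, dtype=float)[:, None]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return b * np.column_stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def _tensors_from_elements(d6: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3) symmetric tensors."""
    out = np.zeros(d6.shape[:-1] + (3, 3), dtype=float)
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def fit_tensor(dwi: DWIVolume, clamp_eps: float = 1e-6) -> TensorField:
    """Log-linear OLS tensor fit per masked voxel.

    Non-positive signals are clamped to ``clamp_eps * S0`` and the voxel is
    flagged in ``valid_mask`` (never silently dropped). S0 is the mean of the
    b=0 volumes.
    """
    scheme = dwi.scheme
    if len(scheme.b0_index) < 1:
        raise ValueError("at least one b=0 volume is required")
    mask = dwi.mask if dwi.mask is not None else np.ones(dwi.signals.shape[:3], bool)
    if not mask.any():
        raise ValueError("mask is empty")

    dwi_idx = scheme.dwi_index
    design = design_matrix(scheme.directions[dwi_idx], scheme.b_values[dwi_idx])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient design: diffusion directions are collinear")
    pinv = np.linalg.pinv(design)

    sig = dwi.signals[mask]  # (n_vox, n_volumes)
    s0 = sig[:, scheme.b0_index].mean(axis=1)
    good = s0 > 0
    s0_safe = np.where(good, s0, 1.0)

    s = sig[:, dwi_idx]
    clamped = s <= 0
    s = np.where(clamped, clamp_eps * s0_safe[:, None], s)
    y = -np.log(s / s0_safe[:, None])  # y_i = b g^T D g
    d6 = y @ pinv.T
    d6[~good] = 0.0

    tensors = np.zeros(mask.shape + (3, 3), dtype=float)
    tensors[mask] = _tensors_from_elements(d6)

    valid = np.zeros_like(mask)
    valid[mask] = good & ~clamped.any(axis=1)
    return TensorField.from_tensors(tensors, mask, valid)


def eigendecompose(tensors: np.ndarray, sym_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigensystem of symmetric tensors: descending eigenvalues, row eigenvectors.

    Each eigenvector's sign is fixed so its first nonzero component is positive
    (downstream angle code is sign-invariant regardless).
    """
    t = np.asarray(tensors, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise ValueError("tensors must have trailing shape (3, 3)")
    scale = np.maximum(np.abs(t).max(axis=(-2, -1), keepdims=True), 1.0)
    if not np.all(np.abs(t - np.swapaxes(t, -1, -2)) <= sym_tol * scale):
        raise ValueError("tensor is not symmetric")
    evals, evecs = np.linalg.eigh(t)  # ascending; columns are eigenvectors
    evals = evals[..., ::-1]
    evecs = np.swapaxes(evecs, -1, -2)[..., ::-1, :]  # rows, descending order
    # deterministic sign: first component with |c| > tol made positive
    tol = 1e-12
    sign = np.where(
        np.abs(evecs[..., 0]) > tol,
        np.sign(evecs[..., 0]),
        np.where(np.abs(evecs[..., 1]) > tol, np.sign(evecs[..., 1]), np.sign(evecs[..., 2])),
    )
    sign = np.where(sign == 0, 1.0, sign)
    return np.ascontiguousarray(evals), evecs * sign[..., None]


def mean_diffusivity(eigenvalues: np.ndarray) -> np.ndarray:
    """MD = (e1 + e2 + e3) / 3."""
    return np.asarray(eigenvalues, dtype=float).mean(axis=-1)


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||; NaN where all eigenvalues are 0."""
    ev = np.asarray(eigenvalues, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(ev - mean, axis=-1)
    den = np.linalg.norm(ev, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den == 0, np.nan, fa)


def rotation_from_affine(affine: np.ndarray) -> np.ndarray:
    """Rotation factor of the affine's 3x3 linear part via polar decomposition."""
    lin = np.asarray(affine, dtype=float)[:3, :3]
    if abs(np.linalg.det(lin)) < 1e-12:
        raise ValueError("affine linear part is singular")
    rot, _stretch = scipy.linalg.polar(lin)
    return rot


def reorient_tensors(field: TensorField, affine: np.ndarray) -> TensorField:
    """Resample a tensor field under a voxel-to-voxel affine and reorient tensors.

    Finite-strain reorientation: D' = R D R^T with R the rotation from the polar
    decomposition of the affine's linear part, so MD and FA are preserved by
    construction. Resampling is nearest-neighbor (no tensor interpolation).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    rot = rotation_from_affine(affine)
    inv = np.linalg.inv(affine)

    shape = field.mask.shape
    out_idx = np.indices(shape).reshape(3, -1)
    src = inv[:3, :3] @ out_idx + inv[:3, 3:4]
    src = np.rint(src).astype(int)
    inside = np.all((src >= 0) & (src < np.array(shape)[:, None]), axis=0)
    src_clip = np.clip(src, 0, np.array(shape)[:, None] - 1)
    sx, sy, sz = src_clip

    def pull(a: np.ndarray, fill=0) -> np.ndarray:
        flat = a[sx, sy, sz]
        flat[~inside] = fill
        return flat.reshape(shape + a.shape[3:])

    tensors = pull(field.tensors)
    tensors = np.einsum("ij,...jk,lk->...il", rot, tensors, rot)
    mask = pull(field.mask.astype(np.uint8)).astype(bool)
    valid = pull(field.valid_mask.astype(np.uint8)).astype(bool)
    return TensorField.from_tensors(tensors, mask, valid)


def measure_snr(
    b0: np.ndarray, tissue_mask: np.ndarray, background_mask: np.ndarray
) -> SnrReport:
    """SNR of a magnitude b=0 image from a tissue ROI and a signal-free background ROI.

    The background of a magnitude image is Rayleigh-distributed, so the Gaussian
    noise level is sigma = std(background) / sqrt(2 - pi/2) (= std / 0.6551).
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not tissue_mask.any() or not background_mask.any():
        raise ValueError("tissue and background masks must be nonempty")
    if np.any(tissue_mask & background_mask):
        raise ValueError("tissue and background masks overlap")
    b0 = np.asarray(b0, dtype=float)
    bg_std = float(b0[background_mask].std())
    if bg_std == 0:
        raise ValueError("zero-variance background: SNR undefined")
    sigma = bg_std / _RAYLEIGH_STD_FACTOR
    mean_signal = float(b0[tissue_mask].mean())
    return SnrReport(mean_signal=mean_signal, noise_sigma=sigma, snr=mean_signal / sigma)
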