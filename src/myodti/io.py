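"""NIfTI and FSL-dialect gradient-table I/O helpers."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
]


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | os.PathLike) -> None:
    """Write an array as a NIfTI volume (dtype preserved; bool stored as uint8)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), os.fspath(path))


def load_nifti(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(os.fspath(path))
    return np.asanyarray(img.dataobj), np.asarray(img.affine)


def write_bvals_bvecs(
    b_values: np.ndarray, directions: np.ndarray, bval_path: str, bvec_path: str
) -> None:
    """Write FSL-dialect gradient tables.

    ``bval``: one row of b-values (s/mm^2), one column per volume.
    ``bvec``: three rows (x, y, z components), one column per volume.
    """
    b = np.atleast_1d(np.asarray(b_values, dtype=float))
    g = np.asarray(directions, dtype=float)
    if g.shape != (b.size, 3):
        raise ValueError(f"directions shape {g.shape} does not match {b.size} b-values")
    np.savetxt(bval_path, b[None, :], fmt="%.6g")
    np.savetxt(bvec_path, g.T, fmt="%.8f")


def read_bvals_bvecs(bval_path: str, bvec_path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect bval/bvec files; returns (b_values (N,), directions (N, 3))."""
    b = np.loadtxt(bval_path).reshape(-1)
    g = np.loadtxt(bvec_path)
    if g.shape[0] == 3 and g.shape != (3, 3):
        g = g.T
    elif g.shape == (3, 3):
        # ambiguous 3x3 table: FSL convention is one column per volume
        g = g.T
    if g.shape != (b.size, 3):
        raise ValueError("bvec table does not match bval count")
    return b, g
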