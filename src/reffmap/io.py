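"""File I/O: FSL gradient tables and NIfTI helpers."""

from __future__ import annotations


import nibabel as nib
import numpy as np

__all__ = [
    "read_bval_bvec",
    "write_bval_bvec",
    "load_nifti",
    "save_nifti",
    "GradientTableError",
]


class GradientTableError(ValueError):
    """Malformed or inconsistent bval/bvec files."""


def read_bval_bvec(bval_path, bvec_path, normalize: bool = True):
    """Read FSL-dialect gradient tables -> (bvals (N,), bvecs (N, 3)).

    bval is a single whitespace row of N floats; bvec is 3 rows of N floats.
    Diffusion directions are re-normalised to unit length (b=0 rows may be
    zero vectors and are left as-is).
    """
    bvals = np.loadtxt(bval_path, ndmin=2)
    if bvals.shape[0] != 1:
        raise GradientTableError(
            f"bval must be a single row, got shape {bvals.shape}"
        )
    bvals = bvals[0]
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise GradientTableError(
            f"bvec must have 3 rows (FSL dialect), got {bvecs.shape[0]}"
        )
    bvecs = bvecs.T
    if bvecs.shape[0] != bvals.shape[0]:
        raise GradientTableError(
            f"bval ({bvals.shape[0]}) and bvec ({bvecs.shape[0]}) "
            "volume counts differ"
        )
    if normalize:
        nrm = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0.5
        bad = dwi & (nrm < 1e-6)
        if np.any(bad):
            raise GradientTableError("zero direction vector on a diffusion volume")
        bvecs[dwi] /= nrm[dwi, None]
    return bvals, bvecs


def write_bval_bvec(bvals, bvecs, bval_path, bvec_path):
    np.savetxt(bval_path, np.asarray(bvals)[None], fmt="%.6g")
    np.savetxt(bvec_path, np.asarray(bvecs).T, fmt="%.10g")


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def save_nifti(arr, affine, path, dtype=np.float32):
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), affine), str(path))
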