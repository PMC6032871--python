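"""Readers and writers for the interchange formats.

Gradient tables use the FSL dialect: a ``bval`` file with one
space-separated row of b-values in s/mm^2 and a ``bvec`` file with three
rows of direction components. Internally b-values are ms/um^2
(= s/mm^2 / 1000). Volumes travel as NIfTI; voxel sets as tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import B0_THRESHOLD, AcquisitionScheme

__all__ = [
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "load_dwi",
    "save_dwi",
    "save_parameter_maps",
    "write_manifest",
]


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    """FSL-dialect gradient table -> scheme (b converted to ms/um^2).

    Zero rows in the bvec file for b=0 volumes are accepted; nonzero
    direction vectors are renormalized.
    """
    bvals = np.loadtxt(bval_path, ndmin=1) / 1000.0
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # ambiguous; FSL writes 3 rows x N columns
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bval/bvec count mismatch: {bvals.size} b-values, {bvecs.shape[0]} vectors"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals > B0_THRESHOLD
    if np.any(norms[dw] == 0):
        raise ValueError("zero direction vector on a diffusion-weighted volume")
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[dw][:, None]
    bvecs[~dw] = 0.0
    return AcquisitionScheme(bvals, bvecs)


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, (scheme.bvals * 1000.0)[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10f")


def load_dwi(nifti_path, bval_path, bvec_path):
    """Load a 4-D DWI volume plus gradient table.

    Returns (scheme, data) with data shaped (X, Y, Z, N). Raises on a
    volume-count mismatch.
    """
    for p in (nifti_path, bval_path, bvec_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    scheme = read_bvals_bvecs(bval_path, bvec_path)
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"volume count mismatch: image has {data.shape[-1] if data.ndim == 4 else '?'}"
            f" volumes, gradient table {scheme.n_volumes}"
        )
    return scheme, data


def save_dwi(nifti_path, data: np.ndarray, scheme: AcquisitionScheme | None = None,
             bval_path=None, bvec_path=None, affine: np.ndarray | None = None) -> None:
    """Write a 4-D DWI NIfTI (identity affine by default) and, optionally,
    its gradient table alongside."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(nifti_path))
    if scheme is not None and bval_path is not None and bvec_path is not None:
        write_bvals_bvecs(scheme, bval_path, bvec_path)


def save_parameter_maps(out_dir, maps: dict, affine: np.ndarray | None = None) -> list:
    """Write each 3-D array in ``maps`` as <out_dir>/<name>.nii.gz."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    written = []
    for name, arr in maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), str(p))
        written.append(p)
    return written


def write_manifest(out_dir, config: dict, seed: int | None = None) -> Path:
    """Record the run configuration, seed, and package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    payload = {"version": __version__, "seed": seed, "config": config}
    path.write_text(json.dumps(payload, indent=2, default=_default, sort_keys=True))
    return path
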