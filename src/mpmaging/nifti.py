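"""NIfTI-1 I/O helpers.

Conventions used throughout the package: 0-based voxel indices, RAS-oriented
affines built from the voxel size (the synthetic cohort lives in a shared
space, so affines are diagonal), data returned as float arrays with voxel
size read back from the affine.  Both plain ``.nii`` and gzipped ``.nii.gz``
files are supported via nibabel.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "make_affine"]


def make_affine(voxel_size_mm) -> np.ndarray:
    """Diagonal RAS affine from a (3,) voxel size in mm."""
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    return affine


def write_volume(path, data, voxel_size_mm=(1.0, 1.0, 1.0), affine=None):
    """Write a 3D/4D array as NIfTI-1; echo/time runs along the 4th axis."""
    if affine is None:
        affine = make_affine(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(np.abs(np.diag(affine)[:3])) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))
    return Path(path)


def read_volume(path):
    """Read a NIfTI file.

    Returns
    -------
    data : ndarray (float)
    affine : (4, 4) ndarray
    voxel_size_mm : tuple of 3 floats (from the header pixdims)
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # malformed header, wrong magic, truncated file
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return data, affine, tuple(float(z) for z in zooms)
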