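"""NIfTI-1 and FSL bval/bvec file I/O.

Voxel coordinates are 0-based array indices internally; the NIfTI affine
governs world space and is copied unchanged to every output.  Data are
stored float32 on disk and computed in float64.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .series import DWISeries

log = logging.getLogger("mpdwi")

__all__ = ["read_dwi", "write_dwi", "write_maps", "read_gradient_table"]


def read_gradient_table(bval_path: str | Path,
                        bvec_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect bval/bvec text files.

    bvec is expected as 3 rows x M columns; an M x 3 (column-major) layout
    is auto-detected by shape and transposed with a logged notice (assuming
    M != 3).  Off-unit b>0 directions are renormalised with a warning when
    the deviation exceeds 1e-3.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        log.info("bvec file %s appears to be M x 3; transposing", bvec_path)
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec file must be 3 x M or M x 3, got {bvecs.shape}")
    bvecs = bvecs.T  # (M, 3)
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval has {bvals.size} entries but bvec has {bvecs.shape[0]}")
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 50
    off = weighted & (np.abs(norms - 1.0) > 1e-3)
    if np.any(off):
        log.warning("renormalising %d bvecs off unit length by > 1e-3",
                    int(off.sum()))
    scale = np.where(weighted & (norms > 0), norms, 1.0)
    return bvals, bvecs / scale[:, None]


def read_dwi(image_path: str | Path, bval_path: str | Path,
             bvec_path: str | Path,
             phase_path: str | Path | None = None) -> DWISeries:
    """Load a 4-D NIfTI series with its gradient table (and optional phase)."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    bvals, bvecs = read_gradient_table(bval_path, bvec_path)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"image has {data.shape[3]} volumes but gradient table has {bvals.size}")
    phase = None
    if phase_path is not None:
        pimg = nib.load(str(phase_path))
        phase = np.asarray(pimg.dataobj, dtype=np.float64)
        if phase.shape != data.shape:
            raise ValueError("phase image shape differs from the magnitude image")
    zooms = img.header.get_zooms()[:3]
    return DWISeries(signal=data, bvals=bvals, bvecs=bvecs, phase=phase,
                     voxel_size=tuple(float(z) for z in zooms),
                     affine=np.asarray(img.affine))


def write_dwi(series: DWISeries, image_path: str | Path,
              bval_path: str | Path | None = None,
              bvec_path: str | Path | None = None,
              phase_path: str | Path | None = None) -> None:
    """Write a series (and optionally its tables/phase) to disk."""
    img = nib.Nifti1Image(series.signal.astype(np.float32), series.affine)
    img.header.set_zooms(series.voxel_size + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        np.savetxt(bval_path, series.bvals[None, :], fmt="%g")
    if bvec_path is not None:
        np.savetxt(bvec_path, series.bvecs.T, fmt="%.10f")
    if phase_path is not None:
        if series.phase is None:
            raise ValueError("series has no phase to write")
        nib.save(nib.Nifti1Image(series.phase.astype(np.float32),
                                 series.affine), str(phase_path))


def write_maps(maps: dict[str, np.ndarray], prefix: str | Path,
               affine: np.ndarray | None = None) -> list[Path]:
    """Write one float32 NIfTI per named map as ``<prefix>_<name>.nii.gz``.

    NaN flag voxels are preserved as NaN.
    """
    affine = np.eye(4) if affine is None else affine
    paths = []
    for name, arr in maps.items():
        path = Path(f"{prefix}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine),
                 str(path))
        paths.append(path)
    return paths
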