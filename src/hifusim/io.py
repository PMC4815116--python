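"""Volume and metrics I/O.

Scalar volumes (heat source, temperature, dose, masks) are written as
NIfTI with the voxel spacing carried in the affine (mm, the NIfTI
convention); lesion metrics go to JSON and per-step diagnostics to CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .grid import CartesianGrid
from .lesion import LesionMetrics

__all__ = ["write_volume", "read_volume", "write_metrics"]

_NIFTI_EXT = (".nii", ".nii.gz")


def write_volume(data: np.ndarray, grid: CartesianGrid, path) -> None:
    """Write a scalar volume as NIfTI with dx in the affine (mm)."""
    import nibabel as nib

    path = Path(path)
    if not any(str(path).endswith(e) for e in _NIFTI_EXT):
        raise ValueError(
            f"unsupported extension for {path.name}; use one of {_NIFTI_EXT}"
        )
    dx_mm = grid.dx * 1e3
    affine = np.diag([dx_mm, dx_mm, dx_mm, 1.0])
    affine[:3, 3] = np.asarray(grid.origin) * 1e3
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms((dx_mm, dx_mm, dx_mm))
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (array, dx in meters)."""
    import nibabel as nib

    img = nib.load(str(path))
    dx_mm = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj, dtype=np.float64), dx_mm * 1e-3


def write_metrics(metrics: LesionMetrics, path) -> None:
    d = asdict(metrics)
    d.pop("mask")
    with open(path, "w") as f:
        json.dump(d, f, indent=2)
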