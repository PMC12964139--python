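"""NIfTI volume I/O.

All volumes are written as NIfTI-1 with an RAS+ diagonal affine carrying
the voxel spacing in mm.  Complex displacement fields are stored as
paired real/imaginary scalar volumes per component, named
``{stem}_{re|im}_{x|y|z}.nii.gz``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

__all__ = ["write_volume", "read_volume", "write_field", "read_field"]


def write_volume(volume: np.ndarray, path: str | Path, spacing_mm: float = 2.0) -> Path:
    path = Path(path)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (data, isotropic spacing in mm)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"{path}: anisotropic voxels {zooms} not supported")
    return data, float(zooms[0])


def check_same_grid(a: np.ndarray, b: np.ndarray, what: str = "volumes") -> None:
    if a.shape != b.shape:
        raise ValueError(f"cannot combine {what} on different grids: {a.shape} vs {b.shape}")


def write_field(data: np.ndarray, stem: str | Path, spacing_mm: float) -> list:
    """Write a complex (nx, ny, nz, 3) field as six scalar volumes."""
    stem = Path(stem)
    paths = []
    for part, arr in (("re", data.real), ("im", data.imag)):
        for c, axis in enumerate("xyz"):
            paths.append(
                write_volume(arr[..., c], stem.parent / f"{stem.name}_{part}_{axis}.nii.gz", spacing_mm)
            )
    return paths


def read_field(stem: str | Path) -> Tuple[np.ndarray, float]:
    stem = Path(stem)
    comps = {}
    spacing = None
    for part in ("re", "im"):
        for c, axis in enumerate("xyz"):
            data, spacing = read_volume(stem.parent / f"{stem.name}_{part}_{axis}.nii.gz")
            comps[(part, c)] = data
    shape = comps[("re", 0)].shape
    out = np.zeros(shape + (3,), dtype=complex)
    for c in range(3):
        out[..., c] = comps[("re", c)] + 1j * comps[("im", c)]
    return out, spacing
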