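"""NIfTI and gradient-table I/O built on nibabel."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["load_volume", "save_volume", "affine_from_voxel_size"]


def affine_from_voxel_size(voxel_size_mm=(2.0, 2.0, 2.0)) -> np.ndarray:
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    return np.diag([vs[0], vs[1], vs[2], 1.0])


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
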