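"""NIfTI volume I/O.

Thin wrappers over nibabel keeping voxel data, affine and voxel spacing
together, with validation for binary masks.  Physical distances and
volumes downstream are always derived from the spacing stored here
(mm per voxel axis); volumes are voxel count x voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class VoxelGrid:
    """A 3-D volume with its affine and voxel spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    @classmethod
    def from_array(cls, data, spacing=(1.0, 1.0, 1.0)) -> "VoxelGrid":
        affine = np.diag(list(spacing) + [1.0])
        return cls(np.asarray(data), tuple(spacing), affine)


def read_volume(path: str | Path, binary: bool = False) -> VoxelGrid:
    """Read a NIfTI-1 volume.

    Parameters
    ----------
    path:
        NIfTI file with affine and voxel-spacing metadata.
    binary:
        Declare the volume a mask; values outside {0, 1} raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(
            f"{path}: voxel-spacing metadata absent or invalid; "
            "refusing distance/volume computations"
        )
    grid = VoxelGrid(data, tuple(float(z) for z in zooms), img.affine)
    if binary and not grid.is_binary():
        bad = np.unique(grid.data[~np.isin(grid.data, (0, 1))])[:5]
        raise ValueError(f"{path}: declared binary mask contains values {bad}")
    return grid


def write_volume(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as NIfTI-1, preserving spacing round-trip."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid.data), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path
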