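"""Voxel-grid primitives shared by all modules.

Everything downstream (phantoms, segmentations, overlap metrics) lives on a
regular 3-D voxel grid with millimetre spacing. Indices are 0-based; a voxel's
volume in cm^3 is ``prod(spacing) / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VoxelGrid"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis; every dimension must be >= 16.
    spacing : tuple of float, default (4, 4, 4)
        Voxel edge lengths in mm, matching a typical clinical PET
        reconstruction grid.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise ValueError("grid is three-dimensional")
        if any(int(n) < 16 for n in self.shape):
            raise ValueError(f"all grid dimensions must be >= 16, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def volume_cm3(self, mask: np.ndarray) -> float:
        """Volume of a binary mask in cm^3."""
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {self.shape}")
        return float(np.count_nonzero(mask)) * self.voxel_volume_cm3

    def zeros(self, dtype=bool) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)
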