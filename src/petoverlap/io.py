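"""NIfTI image/mask I/O, JSON sidecars and the serializable run configuration.

Images are stored as 32-bit float, masks as unsigned 8-bit, both in NIfTI-1
with the voxel spacing on the affine diagonal (RAS+ orientation assumed and
asserted). Masks round-trip losslessly; images round-trip within float32
precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grid import VoxelGrid
from .phantom import PhantomConfig, SimulatedImage

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "require_same_spacing", "write_sidecar", "read_sidecar", "RunConfig",
]


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    if np.any(aff[:3, :3] - np.diag(np.diag(aff[:3, :3])) != 0) or np.any(np.diag(aff)[:3] <= 0):
        raise ValueError("only axis-aligned RAS+ images with positive spacing are supported")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(tuple(int(s) for s in img.shape[:3]), zooms)


def write_image(path, image: SimulatedImage) -> None:
    nii = nib.Nifti1Image(image.values.astype(np.float32),
                          _affine_from_spacing(image.grid.spacing))
    nii.header.set_zooms(image.grid.spacing)
    nib.save(nii, str(path))


def read_image(path) -> SimulatedImage:
    nii = nib.load(str(path))
    grid = _grid_from_nifti(nii)
    values = np.asarray(nii.dataobj, dtype=np.float32).astype(np.float64)
    return SimulatedImage(grid=grid, values=np.clip(values, 0.0, None),
                          meta={"source": str(path)})


def write_mask(path, mask: np.ndarray, grid: VoxelGrid) -> None:
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    nii = nib.Nifti1Image(mask.astype(np.uint8), _affine_from_spacing(grid.spacing))
    nii.header.set_zooms(grid.spacing)
    nib.save(nii, str(path))


def read_mask(path) -> tuple[np.ndarray, VoxelGrid]:
    nii = nib.load(str(path))
    grid = _grid_from_nifti(nii)
    return np.asarray(nii.dataobj) > 0, grid


def require_same_spacing(a: VoxelGrid, b: VoxelGrid, what: str = "paired inputs") -> None:
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"{what} have different voxel spacing: "
                         f"{a.spacing} vs {b.spacing}")


def write_sidecar(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclasses.dataclass
class RunConfig:
    """Everything a full pipeline run needs, YAML round-trippable.

    Every random procedure consumes a named seed: the phantom geometry seed
    lives on ``phantom``, cohort-level draws on ``cohort_seed``.
    """

    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    n_fuzzy: int = 2
    beta: float = 1.0
    register_rotation: bool = False
    cohort_n: int = 19
    cohort_profile: str = "mixed"
    cohort_seed: int = 0
    out_dir: str = "results"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["phantom"]["shape"] = list(self.phantom.shape)
        d["phantom"]["spacing"] = list(self.phantom.spacing)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        ph = d.pop("phantom")
        ph["shape"] = tuple(ph["shape"])
        ph["spacing"] = tuple(ph["spacing"])
        return cls(phantom=PhantomConfig(**ph), **d)
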