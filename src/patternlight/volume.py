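"""Volumetric I/O, coordinate conversion and mask flattening.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)``;
* world (mm) coordinates follow the NIfTI affine (RAS+ expected, not enforced);
* masked vectors store voxels in Fortran linear order (first axis fastest),
  one fixed ordering everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "MaskedVector",
    "read_volume",
    "read_series",
    "write_volume",
    "write_series",
    "voxel_to_mm",
    "mm_to_voxel",
    "apply_mask",
    "unflatten",
]


@dataclass(frozen=True)
class VolumeGrid:
    """3-D sampling grid: dimensions plus a voxel->mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @classmethod
    def isotropic(cls, dims, voxel_mm: float = 2.0) -> "VolumeGrid":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(dims), aff)

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class MaskedVector:
    """Values over a fixed subset of grid voxels.

    ``indices`` are Fortran-order linear indices, strictly increasing;
    ``values`` is aligned to them.
    """

    grid: VolumeGrid
    indices: np.ndarray
    values: np.ndarray = field(default=None)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size == 0:
            raise ValueError("empty mask")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("mask indices must be strictly increasing")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape[-1] != self.indices.size:
                raise ValueError(
                    f"values length {self.values.shape[-1]} != mask size "
                    f"{self.indices.size}"
                )

    @property
    def n(self) -> int:
        return self.indices.size

    def ijk(self) -> np.ndarray:
        """Voxel (i, j, k) coordinates of the mask voxels, shape (n, 3)."""
        return np.stack(np.unravel_index(self.indices, self.grid.dims, order="F"), axis=1)


def read_volume(path, expect_3d: bool = True):
    """Read a NIfTI-1 volume, returning ``(VolumeGrid, data)``.

    Raises ``FileNotFoundError`` for a missing path and ``ValueError`` when a
    4-D file is read with ``expect_3d=True``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if expect_3d and data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    grid = VolumeGrid(tuple(int(d) for d in data.shape[:3]), np.asarray(img.affine))
    return grid, data


def read_series(path):
    """Read a 4-D NIfTI-1 series as ``(VolumeGrid, data[x, y, z, t])``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got shape {data.shape}")
    grid = VolumeGrid(tuple(int(d) for d in data.shape[:3]), np.asarray(img.affine))
    return grid, data


def write_volume(grid: VolumeGrid, values: np.ndarray, path) -> None:
    values = np.asarray(values)
    if values.shape != grid.dims:
        raise ValueError(f"data shape {values.shape} != grid dims {grid.dims}")
    nib.save(nib.Nifti1Image(values.astype(np.float32), grid.affine), str(path))


def write_series(grid: VolumeGrid, values4d: np.ndarray, path) -> None:
    values4d = np.asarray(values4d)
    if values4d.ndim != 4 or values4d.shape[:3] != grid.dims:
        raise ValueError(f"data shape {values4d.shape} incompatible with {grid.dims}")
    nib.save(nib.Nifti1Image(values4d.astype(np.float32), grid.affine), str(path))


def voxel_to_mm(grid: VolumeGrid, ijk) -> np.ndarray:
    """Map 0-based voxel indices to world mm coordinates via the affine."""
    ijk = np.asarray(ijk, dtype=float)
    single = ijk.ndim == 1
    ijk2 = np.atleast_2d(ijk)
    if np.any(ijk2 < 0) or np.any(ijk2 >= np.asarray(grid.dims)):
        raise ValueError("voxel index outside grid")
    xyz = ijk2 @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return xyz[0] if single else xyz


def mm_to_voxel(grid: VolumeGrid, xyz) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm` (continuous voxel coordinates)."""
    xyz = np.asarray(xyz, dtype=float)
    single = xyz.ndim == 1
    xyz2 = np.atleast_2d(xyz)
    inv = np.linalg.inv(grid.affine)
    ijk = xyz2 @ inv[:3, :3].T + inv[:3, 3]
    return ijk[0] if single else ijk


def mask_indices(mask: np.ndarray) -> np.ndarray:
    """Fortran-order linear indices of the True voxels of a 3-D mask."""
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask.ravel(order="F"))
    if idx.size == 0:
        raise ValueError("empty mask")
    return idx


def apply_mask(grid: VolumeGrid, values: np.ndarray, mask: np.ndarray) -> MaskedVector:
    """Flatten a volume (or stack of volumes) to the mask voxels."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.dims:
        raise ValueError("mask shape does not match grid")
    idx = mask_indices(mask)
    if values.shape[-3:] != grid.dims:
        raise ValueError("values shape does not match grid")
    flat = values.reshape(values.shape[:-3] + (-1,), order="F") if values.ndim > 3 \
        else values.ravel(order="F")
    return MaskedVector(grid, idx, flat[..., idx])


def unflatten(mv: MaskedVector, fill: float = 0.0) -> np.ndarray:
    """Place masked values back on the full grid, ``fill`` elsewhere."""
    out = np.full(mv.grid.n_voxels, fill, dtype=float)
    out[mv.indices] = mv.values
    return out.reshape(mv.grid.dims, order="F")
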