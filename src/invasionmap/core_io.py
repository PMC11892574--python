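"""Volume data model and NIfTI input/output.

All stages of the invasion-mapping pipeline operate on volumes sharing a
single voxel grid: binary masks (tumor, white matter), scalar parametric
maps (the 12 DKI-derived maps or any co-registered scalar volume), and the
per-voxel diffusion tensor field.  This module defines those containers,
reads and writes them as NIfTI-1, and validates that a set of volumes is
actually co-registered before any analysis runs.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)`` triples in array axis order;
  world coordinates exist only through the affine.
* Tensor volumes carry 6 components on the 4th axis in
  lower-triangular-by-row order ``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)``
  (units mm^2/s).  The alternative diagonal-first dialect
  ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` can be remapped on read.
* Masks are binarized on read (any nonzero value is inside) and written
  as uint8 {0, 1}; scalar outputs are float32 with NaN marking excluded
  voxels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "BinaryMask",
    "ScalarMap",
    "TensorField",
    "TENSOR_ORDER_LOWER_TRIANGULAR",
    "TENSOR_ORDER_DIAGONAL_FIRST",
    "PARAMETRIC_MAP_NAMES",
    "read_volume",
    "write_volume",
    "validate_grids",
]

#: Canonical internal tensor component order (lower triangular by row).
TENSOR_ORDER_LOWER_TRIANGULAR = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
#: The other common dialect (diagonal first), remappable on read.
TENSOR_ORDER_DIAGONAL_FIRST = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

#: Index permutation taking diagonal-first storage to the canonical order.
_DIAG_FIRST_TO_LT = np.array([0, 3, 4, 1, 5, 2])

#: The DKI-derived scalar maps named in the method; "other" covers any
#: further co-registered scalar volume (relaxometry, PET, perfusion ...).
PARAMETRIC_MAP_NAMES = (
    "MD", "FA", "MK", "AK", "RK", "KA", "AWF",
    "AxEAD", "AxIAD", "RadEAD", "RadIAD", "TORT", "other",
)


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D sampling grid: shape, voxel size (mm), and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be 3 positive lengths, got {self.voxel_size}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or not np.all(np.isfinite(affine)):
            raise ValueError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_img(cls, img: nib.Nifti1Image) -> "VoxelGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(tuple(img.shape[:3]), tuple(float(z) for z in zooms), img.affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "VoxelGrid", tol_mm: float = 0.01) -> bool:
        """True when shapes are equal and affines agree within ``tol_mm`` per element."""
        return self.shape == other.shape and bool(
            np.all(np.abs(self.affine - other.affine) <= tol_mm)
        )


@dataclass
class BinaryMask:
    """A boolean volume (tumor mask, white-matter mask, truth mask ...)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


@dataclass
class ScalarMap:
    """A scalar volume: one of the DKI parametric maps, or any co-registered map.

    Units depend on the map (mm^2/s for MD and the diffusivities,
    dimensionless for the kurtosis metrics, FA, AWF and TORT).
    """

    grid: VoxelGrid
    values: np.ndarray
    name: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"map shape {self.values.shape} does not match grid {self.grid.shape}"
            )


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor, 6 unique components (mm^2/s).

    ``components`` has shape ``grid.shape + (6,)`` in the canonical
    lower-triangular-by-row order (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
    """

    grid: VoxelGrid
    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError(
                f"tensor shape {self.components.shape} does not match "
                f"grid {self.grid.shape} + (6,)"
            )

    def as_matrices(self, flat_indices: np.ndarray | None = None) -> np.ndarray:
        """Reconstruct full symmetric 3x3 matrices.

        Parameters
        ----------
        flat_indices : optional flat voxel indices; when given, only those
            voxels' tensors are returned (shape ``(n, 3, 3)``), otherwise
            all voxels (shape ``grid.shape + (3, 3)``).
        """
        c = self.components.reshape(-1, 6)
        if flat_indices is not None:
            c = c[np.asarray(flat_indices)]
        out = np.empty(c.shape[:-1] + (3, 3), dtype=np.float64)
        out[..., 0, 0] = c[..., 0]
        out[..., 0, 1] = out[..., 1, 0] = c[..., 1]
        out[..., 0, 2] = out[..., 2, 0] = c[..., 2]
        out[..., 1, 1] = c[..., 3]
        out[..., 1, 2] = out[..., 2, 1] = c[..., 4]
        out[..., 2, 2] = c[..., 5]
        if flat_indices is None:
            out = out.reshape(self.grid.shape + (3, 3))
        return out


Volume = Union[BinaryMask, ScalarMap, TensorField]


def read_volume(
    path: str | os.PathLike,
    expected_kind: Literal["mask", "scalar", "tensor"],
    *,
    tensor_order: Literal["lower_triangular", "diagonal_first"] = "lower_triangular",
    name: str = "other",
) -> Volume:
    """Read a NIfTI volume as the requested typed container.

    Masks and scalar maps must be 3-D (a trailing singleton 4th axis is
    squeezed); tensor volumes must carry exactly 6 components on the 4th
    axis.  Masks binarize any nonzero voxel to True.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.all(np.isfinite(img.affine)):
        raise ValueError(f"non-finite affine in {path}")
    grid = VoxelGrid.from_img(img)

    if expected_kind == "tensor":
        if data.ndim != 4 or data.shape[3] != 6:
            raise ValueError(
                f"{path}: expected a 4-D volume with 6 tensor components, "
                f"got shape {data.shape}"
            )
        comps = np.asarray(data, dtype=np.float64)
        if tensor_order == "diagonal_first":
            comps = comps[..., _DIAG_FIRST_TO_LT]
        elif tensor_order != "lower_triangular":
            raise ValueError(f"unknown tensor order {tensor_order!r}")
        return TensorField(grid, comps)

    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D {expected_kind} volume, got shape {data.shape}"
        )
    if expected_kind == "mask":
        return BinaryMask(grid, data != 0)
    if expected_kind == "scalar":
        return ScalarMap(grid, data, name=name)
    raise ValueError(f"unknown expected_kind {expected_kind!r}")


def write_volume(volume: Volume | np.ndarray, path: str | os.PathLike,
                 grid: VoxelGrid | None = None, dtype=None) -> None:
    """Write a typed volume (or a raw array plus grid) as NIfTI.

    Masks are stored as uint8 {0,1}; scalar maps as float32 unless an
    explicit dtype is given.  The parent directory must already exist.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    if isinstance(volume, BinaryMask):
        data, grid = volume.values.astype(np.uint8), volume.grid
        dtype = dtype or np.uint8
    elif isinstance(volume, ScalarMap):
        data, grid = volume.values, volume.grid
        dtype = dtype or np.float32
    elif isinstance(volume, TensorField):
        data, grid = volume.components, volume.grid
        dtype = dtype or np.float32
    else:
        data = np.asarray(volume)
        if grid is None:
            raise ValueError("a VoxelGrid is required when writing a raw array")
        dtype = dtype or np.float32
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    img.header.set_zooms(grid.voxel_size + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def validate_grids(volumes: Sequence[Volume], tol_mm: float = 0.01) -> VoxelGrid:
    """Return the common grid of co-registered volumes, or raise.

    All shapes must be identical and all affines must agree element-wise
    within ``tol_mm`` (default 0.01 mm — small resampling jitter from the
    external co-registration must not abort a run, genuine misalignment
    must).
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("no volumes given")
    ref = volumes[0].grid
    for v in volumes[1:]:
        g = v.grid
        if g.shape != ref.shape:
            raise ValueError(
                f"grids not co-registered: shape {g.shape} differs from {ref.shape}"
            )
        if not ref.matches(g, tol_mm=tol_mm):
            raise ValueError(
                "grids not co-registered: affines differ by more than "
                f"{tol_mm} mm per element"
            )
    return ref
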