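"""Step-count distance map from the tumor border through the white matter.

The white matter forms a "labyrinth" in which all analysis is confined.
Every white-matter voxel is labeled with the minimal number of single-voxel
steps (26-connected; a diagonal step also counts 1) needed to reach a voxel
adjacent to the tumor: tumor-adjacent white-matter voxels get d = 1, their
unlabeled white-matter neighbors d = 2, and so on, iterating until no voxel
can be added.  This is *not* a Euclidean distance — it is the length of the
shortest voxel path inside the mask.

White-matter components not connected to the tumor are never labeled and are
excluded from all downstream analysis (marked ``UNREACHABLE``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, VoxelGrid, validate_grids

__all__ = ["UNREACHABLE", "DistanceMap", "compute_distance_map", "eligible_voxels"]

#: Marker for voxels carrying no distance (non-white-matter, tumor, or
#: white matter disconnected from the tumor).
UNREACHABLE: int = -1

#: 3x3x3 all-ones structuring element = 26-connectivity.
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class DistanceMap:
    """Per-voxel step count to the tumor border inside the white matter.

    ``d`` is an int32 volume; eligible voxels carry d >= 1, everything else
    (tumor, background, disconnected white matter) carries ``UNREACHABLE``.
    """

    grid: VoxelGrid
    d: np.ndarray
    d_max: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.int32)
        if self.d.shape != self.grid.shape:
            raise ValueError("distance volume shape does not match grid")

    @property
    def eligible(self) -> np.ndarray:
        """Boolean volume of voxels with a finite distance."""
        return self.d != UNREACHABLE

    @property
    def n_eligible(self) -> int:
        return int(np.count_nonzero(self.d != UNREACHABLE))


def compute_distance_map(
    wm: BinaryMask,
    tumor: BinaryMask,
    connectivity: int = 26,
) -> DistanceMap:
    """Iteratively label white-matter voxels by step distance to the tumor.

    The first iteration labels white-matter voxels adjacent to the tumor
    with 1; each following iteration labels the unlabeled white-matter
    neighbors of the previous front, until no voxel can be placed.  Voxels
    of the white-matter mask that also lie inside the tumor mask are treated
    as tumor (removed from the white matter before labeling).

    Parameters
    ----------
    wm, tumor : binary masks on a common grid.
    connectivity : 6, 18 or 26 — which lattice neighbors count as adjacent
        (one voxel per step in every case).  Default 26, matching the 26
        transition directions used for the walks.

    Raises
    ------
    ValueError : empty tumor or white-matter mask, or no white-matter voxel
        adjacent to the tumor (the map would be empty and d_max undefined).
    """
    grid = validate_grids([wm, tumor])
    if tumor.n_true == 0:
        raise ValueError("tumor mask is empty")
    wm_vals = wm.values & ~tumor.values  # overlap resolved in favor of tumor
    if not wm_vals.any():
        raise ValueError("white-matter mask is empty (after removing tumor overlap)")

    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])

    d = np.full(grid.shape, UNREACHABLE, dtype=np.int32)
    front = ndimage.binary_dilation(tumor.values, structure=struct) & wm_vals
    if not front.any():
        raise ValueError("no white-matter voxel is adjacent to the tumor")
    level = 0
    labeled = np.zeros(grid.shape, dtype=bool)
    while front.any():
        level += 1
        d[front] = level
        labeled |= front
        front = ndimage.binary_dilation(front, structure=struct) & wm_vals & ~labeled
    return DistanceMap(grid=grid, d=d, d_max=level)


def eligible_voxels(dm: DistanceMap) -> np.ndarray:
    """Voxel indices (n, 3) of the analysis domain: all finite-distance voxels.

    Disconnected white-matter islands carry no distance and are excluded;
    every downstream stage (transition matrices, walks, statistics) operates
    on exactly this set.
    """
    return np.argwhere(dm.d != UNREACHABLE)
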