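"""Directional diffusivity and the per-voxel 26-way transition matrices.

For each eligible white-matter voxel *i* the 26 lattice neighbors *j* are
scored by the apparent diffusion coefficient along the unit direction
``n_ij`` from *i* to *j*::

    ADC_ij = n_ij^T D_i n_ij            (mm^2/s, clamped at 0)

where ``D_i`` is the voxel's symmetric diffusion tensor.  A gate coefficient
``m_ij`` zeroes directions that leave the eligible white matter, and — in
*toward-tumor* mode — directions for which the neighbor's step distance to
the tumor is larger than the voxel's own (``d_j > d_i``); the *away* mode
instead zeroes ``d_j < d_i``.  Equal-distance neighbors remain admissible in
both modes, which is what lets a walk wander sideways along an isodistance
shell.  The step probabilities are::

    W_ij = m_ij ADC_ij / sum_j m_ij ADC_ij

materialized once per run as a dense (n_eligible, 26) matrix.  Gated-in
ADC values are floored at a small epsilon (default 1e-6 mm^2/s, three
orders of magnitude below typical white-matter diffusivity) so that a noisy
tensor can never produce an all-zero row where an admissible neighbor
exists — walks cannot dead-end for numerical reasons.  A row is all-zero
(terminal) only when no admissible neighbor exists at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_io import TensorField, VoxelGrid
from .distance import UNREACHABLE, DistanceMap

__all__ = [
    "ADC_FLOOR",
    "NeighborhoodModel",
    "TransitionWeights",
    "directional_adc",
    "build_transition_matrix",
]

#: Minimum directional ADC (mm^2/s) credited to an admissible neighbor.
ADC_FLOOR: float = 1e-6


def _make_offsets() -> np.ndarray:
    offs = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    return np.array(offs, dtype=np.int64)


@dataclass(frozen=True)
class NeighborhoodModel:
    """The 26-neighbor lattice stencil and its unit direction vectors."""

    offsets: np.ndarray = field(default_factory=_make_offsets)

    @property
    def directions(self) -> np.ndarray:
        """(26, 3) unit vectors n_ij = offset / |offset|."""
        offs = self.offsets.astype(np.float64)
        return offs / np.linalg.norm(offs, axis=1, keepdims=True)

    def opposite_index(self, k: int) -> int:
        """Index of the negated offset (the stencil is closed under negation)."""
        return 25 - k  # lexicographic enumeration of {-1,0,1}^3 \ {0} is antisymmetric

    def __len__(self) -> int:
        return len(self.offsets)


#: Module-level stencil shared by all stages.
NEIGHBORHOOD = NeighborhoodModel()


@dataclass
class TransitionWeights:
    """Dense (n_eligible, 26) transition model for one walk mode.

    Attributes
    ----------
    mode : ``"toward_tumor"`` or ``"away_from_tumor"``.
    elig_flat : flat volume indices of the eligible voxels (row order).
    vol_to_row : int32 volume-sized flat array mapping a voxel's flat index
        to its row (−1 for ineligible voxels).
    neighbor_row : (n, 26) int32 — row index of each neighbor, −1 when the
        neighbor is outside the grid or ineligible.
    m : (n, 26) bool gate coefficients.
    adc : (n, 26) float64 directional ADC (clamped at 0, before flooring).
    W : (n, 26) float64 probabilities; each row sums to 1 or is all zero.
    """

    grid: VoxelGrid
    mode: Literal["toward_tumor", "away_from_tumor"]
    elig_flat: np.ndarray
    vol_to_row: np.ndarray
    neighbor_row: np.ndarray
    m: np.ndarray
    adc: np.ndarray
    W: np.ndarray

    @property
    def n_eligible(self) -> int:
        return len(self.elig_flat)

    def row_of_voxel(self, ijk) -> int:
        """Row index of an (i, j, k) voxel; raises for ineligible voxels."""
        flat = int(np.ravel_multi_index(tuple(int(c) for c in ijk), self.grid.shape))
        row = int(self.vol_to_row[flat])
        if row < 0:
            raise ValueError(f"voxel {tuple(ijk)} is not in the eligible set")
        return row


def directional_adc(tensor: np.ndarray, direction: np.ndarray, *,
                    tol: float = 1e-9) -> float:
    """ADC along a unit direction: the quadratic form n^T D n, clamped >= 0.

    ``tensor`` is a symmetric 3x3 matrix in mm^2/s; ``direction`` must have
    unit Euclidean norm (within ``tol``).
    """
    n = np.asarray(direction, dtype=np.float64)
    if abs(np.linalg.norm(n) - 1.0) > tol:
        raise ValueError(f"direction must be a unit vector, |n| = {np.linalg.norm(n)}")
    D = np.asarray(tensor, dtype=np.float64)
    return max(0.0, float(n @ D @ n))


def build_transition_matrix(
    tensors: TensorField,
    dm: DistanceMap,
    mode: Literal["toward_tumor", "away_from_tumor"],
    *,
    adc_floor: float = ADC_FLOOR,
) -> TransitionWeights:
    """Construct the dense n_eligible x 26 probabilistic transition matrix.

    For every eligible voxel the 26 neighbors are gated by mask membership
    and the mode's distance rule (strict inequalities only — equal-distance
    neighbors stay admissible), scored by directional ADC, floored, and
    normalized to probabilities.  Rows of voxels with no admissible
    neighbor, and rows of ineligible voxels, are all-zero.
    """
    if mode not in ("toward_tumor", "away_from_tumor"):
        raise ValueError(f"unknown mode {mode!r}")
    if tensors.grid.shape != dm.grid.shape:
        raise ValueError("tensor field and distance map are on different grids")

    shape = dm.grid.shape
    d_flat = dm.d.reshape(-1)
    elig_flat = np.flatnonzero(d_flat != UNREACHABLE)
    if elig_flat.size == 0:
        raise ValueError("eligible voxel set is empty")
    n = elig_flat.size

    vol_to_row = np.full(d_flat.size, -1, dtype=np.int32)
    vol_to_row[elig_flat] = np.arange(n, dtype=np.int32)

    coords = np.stack(np.unravel_index(elig_flat, shape), axis=1)  # (n, 3)
    offsets = NEIGHBORHOOD.offsets
    dirs = NEIGHBORHOOD.directions

    # Directional ADC for all 26 stencil directions at once:
    # adc[:, k] = n_k^T D_i n_k, using the 6 unique tensor components.
    c = tensors.components.reshape(-1, 6)[elig_flat]
    nx, ny, nz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    quad = np.stack([nx * nx, 2 * nx * ny, 2 * nx * nz,
                     ny * ny, 2 * ny * nz, nz * nz], axis=1)  # (26, 6)
    adc = np.maximum(c @ quad.T, 0.0)  # (n, 26), clamped

    neighbor_row = np.full((n, 26), -1, dtype=np.int32)
    m = np.zeros((n, 26), dtype=bool)
    d_here = d_flat[elig_flat]
    for k in range(26):
        nb = coords + offsets[k]
        inside = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        nb_flat = np.ravel_multi_index(
            (nb[inside, 0], nb[inside, 1], nb[inside, 2]), shape
        )
        rows = vol_to_row[nb_flat]
        neighbor_row[inside, k] = rows
        ok = np.zeros(n, dtype=bool)
        valid = rows >= 0
        d_nb = np.full(inside.sum(), UNREACHABLE, dtype=np.int64)
        d_nb[valid] = d_flat[nb_flat[valid]]
        if mode == "toward_tumor":
            gate = valid & (d_nb <= d_here[inside])
        else:
            gate = valid & (d_nb >= d_here[inside])
        ok[np.flatnonzero(inside)[gate]] = True
        m[:, k] = ok

    w = np.where(m, np.maximum(adc, adc_floor), 0.0)
    norm = w.sum(axis=1, keepdims=True)
    W = np.divide(w, norm, out=np.zeros_like(w), where=norm > 0)

    return TransitionWeights(
        grid=dm.grid, mode=mode, elig_flat=elig_flat, vol_to_row=vol_to_row,
        neighbor_row=neighbor_row, m=m, adc=adc, W=W,
    )
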