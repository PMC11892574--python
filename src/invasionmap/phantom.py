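"""Synthetic phantoms with planted ground truth for every pipeline stage.

Real inputs to the method are a segmented brain: a white-matter mask forming
a corridor "labyrinth", a tumor mask, a diffusion-tensor field whose
principal axis follows the fiber corridors, and DKI-style parametric maps.
No imaging data ship with this package, so the phantoms emulate exactly
those structural features on a lattice:

* **corridor** — a straight white-matter tube ending at a spherical tumor;
  the minimal geometry where every walk step is forced or near-forced.
* **labyrinth** — a randomized connected 3-D corridor maze (spanning-tree
  carving) around a spherical tumor with a solid perifocal white-matter
  shell; the realistic stand-in for the white-matter labyrinth.
* **shell** — a solid white-matter ball around the tumor with radially
  oriented tensors; large eligible sets with trivial geometry.

Tensors are cigar-shaped with principal diffusivity ``lambda_parallel``
along the local corridor direction and ``lambda_perp`` across it (defaults
1.7e-3 / 0.3e-3 mm^2/s, typical healthy white matter), symmetric positive
definite by construction.

The parametric map is a constant baseline plus, in *glioblastoma* mode, a
planted invasion signature: a ramp of height ``map_contrast`` at the tumor
border decaying linearly to zero over ``gradient_extent`` steps of the
distance map — emulating parameter changes extending beyond the tumor into
(and past) the perifocal zone.  *Metastasis* mode plants nothing outside
the tumor: pure vasogenic edema with no infiltrative component.  Additive
Gaussian noise of sd ``noise_sigma`` emulates thermal noise on the map.
The returned truth mask marks the planted-ramp voxels.

What the phantoms do **not** model: partial-volume effects, curved
sub-voxel fiber geometry, DKI fitting noise correlated across maps, gray
matter and CSF compartments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .core_io import BinaryMask, ScalarMap, TensorField, VoxelGrid
from .distance import UNREACHABLE, compute_distance_map
from .transitions import NEIGHBORHOOD

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom",
           "make_two_slice_crossing_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom; defaults give a realistic run.

    Lengths are voxels unless noted.  ``lambda_parallel``/``lambda_perp``
    are mm^2/s; ``map_baseline``/``map_contrast``/``noise_sigma`` are in
    the (dimensionless, kurtosis-like) units of the parametric map.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    geometry: Literal["corridor", "labyrinth", "shell"] = "labyrinth"
    tumor_radius: float = 4.0
    edema_radius: float = 6.0
    mode: Literal["glioblastoma", "metastasis"] = "glioblastoma"
    lambda_parallel: float = 1.7e-3
    lambda_perp: float = 0.3e-3
    map_baseline: float = 0.8
    map_contrast: float = 0.3
    gradient_extent: int = 5
    noise_sigma: float = 0.03
    seed: int = 0
    corridor_width: int = 1
    tensor_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.edema_radius < self.tumor_radius:
            raise ValueError("edema_radius must be >= tumor_radius")
        if self.mode not in ("glioblastoma", "metastasis"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.geometry not in ("corridor", "labyrinth", "shell"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if min(self.lambda_parallel, self.lambda_perp) <= 0:
            raise ValueError("tensor eigenvalues must be positive")
        if self.gradient_extent < 1:
            raise ValueError("gradient_extent must be >= 1")


@dataclass
class PhantomBundle:
    """Everything a phantom run produces, on one shared grid."""

    wm: BinaryMask
    tumor: BinaryMask
    tensors: TensorField
    pmap: ScalarMap
    truth: BinaryMask
    spec: PhantomSpec


def _ball(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2


def _maze_mask(shape, rng: np.random.Generator) -> np.ndarray:
    """Connected 3-D corridor maze: randomized-Prim spanning tree carved on a
    pitch-2 cell lattice (cells at odd coordinates, one wall voxel between)."""
    ncell = tuple((s - 1) // 2 for s in shape)
    if min(ncell) < 2:
        raise ValueError(f"grid {shape} too small for a labyrinth")
    mask = np.zeros(shape, dtype=bool)

    def cell_voxel(c):
        return tuple(2 * ci + 1 for ci in c)

    in_tree = np.zeros(ncell, dtype=bool)
    start = tuple(ci // 2 for ci in ncell)
    in_tree[start] = True
    mask[cell_voxel(start)] = True
    # frontier edges: (cell_in_tree, neighbor_cell)
    axes = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

    def neighbors(c):
        for a in axes:
            nb = tuple(ci + ai for ci, ai in zip(c, a))
            if all(0 <= ni < li for ni, li in zip(nb, ncell)):
                yield nb

    frontier = [(start, nb) for nb in neighbors(start)]
    while frontier:
        idx = int(rng.integers(len(frontier)))
        frontier[idx], frontier[-1] = frontier[-1], frontier[idx]
        src, dst = frontier.pop()
        if in_tree[dst]:
            continue
        in_tree[dst] = True
        sv, dv = cell_voxel(src), cell_voxel(dst)
        wall = tuple((a + b) // 2 for a, b in zip(sv, dv))
        mask[dv] = True
        mask[wall] = True
        frontier.extend((dst, nb) for nb in neighbors(dst) if not in_tree[nb])
    return mask


def _pca_orientations(wm: np.ndarray) -> np.ndarray:
    """Principal corridor direction per white-matter voxel.

    The direction is the leading eigenvector of the second-moment matrix of
    unit offsets to in-mask 26-neighbors — exactly the tube axis for
    straight corridors.  Voxels with no in-mask neighbor fall back to +x.
    Returns an (n_wm, 3) array over ``np.argwhere(wm)`` order.
    """
    shape = wm.shape
    moments = np.zeros(shape + (6,), dtype=np.float64)  # xx,xy,xz,yy,yz,zz
    offs = NEIGHBORHOOD.offsets
    dirs = NEIGHBORHOOD.directions
    for k in range(26):
        u = dirs[k]
        shifted = _shift(wm, offs[k])
        contrib = np.array([u[0] * u[0], u[0] * u[1], u[0] * u[2],
                            u[1] * u[1], u[1] * u[2], u[2] * u[2]])
        moments[shifted] += contrib
    m = moments[wm]
    M = np.zeros((len(m), 3, 3))
    M[:, 0, 0] = m[:, 0]
    M[:, 0, 1] = M[:, 1, 0] = m[:, 1]
    M[:, 0, 2] = M[:, 2, 0] = m[:, 2]
    M[:, 1, 1] = m[:, 3]
    M[:, 1, 2] = M[:, 2, 1] = m[:, 4]
    M[:, 2, 2] = m[:, 5]
    _, vecs = np.linalg.eigh(M)
    axis = np.array(vecs[:, :, 2])  # leading eigenvector
    trivial = np.abs(m).sum(axis=1) == 0  # no in-mask neighbor
    axis[trivial] = (1.0, 0.0, 0.0)
    return axis


def _shift(mask: np.ndarray, off) -> np.ndarray:
    """Voxels whose neighbor at +off lies inside ``mask`` (no wraparound)."""
    out = np.zeros_like(mask)
    src = tuple(slice(max(o, 0), s + min(o, 0)) for o, s in zip(off, mask.shape))
    dst = tuple(slice(max(-o, 0), s + min(-o, 0)) for o, s in zip(off, mask.shape))
    out[dst] = mask[src]
    return out


def _tensors_from_axes(shape, wm, axes, spec, rng) -> np.ndarray:
    lam_par, lam_perp = spec.lambda_parallel, spec.lambda_perp
    comps = np.zeros(shape + (6,), dtype=np.float64)
    # isotropic floor everywhere keeps off-mask tensors positive definite
    comps[..., 0] = comps[..., 3] = comps[..., 5] = lam_perp
    v = axes
    delta = lam_par - lam_perp
    idx = wm
    comps[idx, 0] += delta * v[:, 0] * v[:, 0]
    comps[idx, 1] = delta * v[:, 0] * v[:, 1]
    comps[idx, 2] = delta * v[:, 0] * v[:, 2]
    comps[idx, 3] += delta * v[:, 1] * v[:, 1]
    comps[idx, 4] = delta * v[:, 1] * v[:, 2]
    comps[idx, 5] += delta * v[:, 2] * v[:, 2]
    if spec.tensor_noise_sigma > 0:
        comps += rng.normal(0.0, spec.tensor_noise_sigma, size=comps.shape)
    return comps


def _finalize(spec: PhantomSpec, wm_vals: np.ndarray, tumor_vals: np.ndarray,
              axes: np.ndarray, rng: np.random.Generator,
              planted: np.ndarray | None = None) -> PhantomBundle:
    """Assemble masks, tensors, parametric map and truth from raw geometry.

    ``planted`` optionally gives an explicit planted-elevation field s in
    [0, 1] (two-slice phantom); otherwise the glioblastoma ramp is built
    from the step-distance map.
    """
    grid = VoxelGrid(spec.grid_shape, spec.voxel_size, _default_affine(spec))
    wm_vals = wm_vals & ~tumor_vals
    wm = BinaryMask(grid, wm_vals)
    tumor = BinaryMask(grid, tumor_vals)
    # validates tumor-white-matter adjacency and connectivity
    dm = compute_distance_map(wm, tumor)

    comps = _tensors_from_axes(grid.shape, wm_vals, axes, spec, rng)
    tensors = TensorField(grid, comps)

    pvals = np.full(grid.shape, spec.map_baseline, dtype=np.float64)
    truth_vals = np.zeros(grid.shape, dtype=bool)
    if spec.mode == "glioblastoma":
        if planted is None:
            d = dm.d.astype(np.float64)
            ramp = np.clip((spec.gradient_extent - (d - 1)) / spec.gradient_extent,
                           0.0, 1.0)
            ramp[dm.d == UNREACHABLE] = 0.0
            planted = ramp
        pvals += spec.map_contrast * planted
        truth_vals = planted > 0
    if spec.noise_sigma > 0:
        pvals += rng.normal(0.0, spec.noise_sigma, size=grid.shape)
    pmap = ScalarMap(grid, pvals, name="MK")
    return PhantomBundle(wm=wm, tumor=tumor, tensors=tensors, pmap=pmap,
                         truth=BinaryMask(grid, truth_vals), spec=spec)


def _default_affine(spec: PhantomSpec) -> np.ndarray:
    aff = np.diag(list(spec.voxel_size) + [1.0])
    return aff


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomBundle:
    """Build the phantom bundle for the requested geometry.

    Same seed, same spec → bit-identical bundle.  Raises when the geometry
    leaves the tumor without any adjacent white matter.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    center = tuple(s // 2 for s in shape)

    if spec.geometry == "corridor":
        cy, cz = shape[1] // 2, shape[2] // 2
        r = spec.tumor_radius
        tcenter = (int(r) + 1, cy, cz)
        tumor_vals = _ball(shape, tcenter, r)
        wm_vals = np.zeros(shape, dtype=bool)
        half = (spec.corridor_width - 1) // 2
        ylo, yhi = cy - half, cy - half + spec.corridor_width
        wm_vals[1:shape[0] - 1, ylo:yhi, cz:cz + 1] = True
        wm_for_axes = wm_vals & ~tumor_vals
        axes = _pca_orientations(wm_for_axes)
    elif spec.geometry == "labyrinth":
        maze = _maze_mask(shape, rng)
        tumor_vals = _ball(shape, center, spec.tumor_radius)
        shell = _ball(shape, center, spec.edema_radius)
        wm_vals = maze | shell
        wm_for_axes = wm_vals & ~tumor_vals
        axes = _pca_orientations(wm_for_axes)
    else:  # shell
        outer = min(shape) // 2 - 2
        tumor_vals = _ball(shape, center, spec.tumor_radius)
        wm_vals = _ball(shape, center, outer)
        wm_for_axes = wm_vals & ~tumor_vals
        coords = np.argwhere(wm_for_axes).astype(np.float64)
        radial = coords - np.array(center, dtype=np.float64)
        norms = np.linalg.norm(radial, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        axes = radial / norms

    return _finalize(spec, wm_vals, tumor_vals, axes, rng)


def make_two_slice_crossing_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomBundle:
    """Two planar corridor systems on different axial slices, joined by an
    oblique bridge — the geometry where no single slice reveals the gradient.

    The tumor sits in the lower plane; the planted elevation (glioblastoma
    mode) is constant over the tumor-plane corridor system, decays linearly
    across the bridge, and is zero over the far-plane system, so every
    single-slice view of the parametric map is flat while profiles along
    through-bridge trajectories carry a significant gradient.  The truth
    mask marks the bridge (ramp) voxels.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    nx, ny, nz = shape
    cy = ny // 2
    bx = nx // 2
    rise = min(nz // 2, nx - 3 - bx)
    if rise < 3:
        raise ValueError(f"grid {shape} too small for the two-slice bridge")
    z1 = (nz - rise) // 2
    z2 = z1 + rise
    r = spec.tumor_radius
    tcenter = (int(r) + 1, cy, z1)
    tumor_vals = _ball(shape, tcenter, r)

    wm_vals = np.zeros(shape, dtype=bool)
    # plane-1 system: main x-corridor plus a y-cross
    wm_vals[1:bx + 1, cy, z1] = True
    wm_vals[bx // 2, max(1, cy - ny // 4):min(ny - 1, cy + ny // 4), z1] = True
    # oblique bridge, one +x+z diagonal step per voxel
    sdist = np.zeros(shape, dtype=np.float64)  # planted elevation s
    for t in range(1, rise + 1):
        wm_vals[bx + t, cy, z1 + t] = True
    # plane-2 system: x-corridor onward plus a y-cross
    x2 = bx + rise
    wm_vals[x2:nx - 1, cy, z2] = True
    wm_vals[min(nx - 2, x2 + (nx - x2) // 2),
            max(1, cy - ny // 4):min(ny - 1, cy + ny // 4), z2] = True

    # planted elevation: 1 on the tumor plane, linear decay across the bridge
    sdist[:, :, z1] = 1.0
    for t in range(1, rise + 1):
        sdist[bx + t, cy, z1 + t] = 1.0 - t / rise
    planted = np.where(wm_vals | tumor_vals, sdist, 0.0)
    truth_region = np.zeros(shape, dtype=bool)
    for t in range(1, rise + 1):
        truth_region[bx + t, cy, z1 + t] = True

    wm_for_axes = wm_vals & ~tumor_vals
    axes = _pca_orientations(wm_for_axes)
    bundle = _finalize(spec, wm_vals, tumor_vals, axes, rng,
                       planted=planted if spec.mode == "glioblastoma" else None)
    # the informative truth for this phantom is the bridge, not every
    # nonzero-elevation voxel
    if spec.mode == "glioblastoma":
        bundle.truth = BinaryMask(bundle.wm.grid, truth_region)
    return bundle
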