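"""Shared fixtures: small phantoms and one full default-configuration run.

Everything is generated programmatically with fixed seeds; nothing is read
from disk.  The module-scope ``gbm_run`` fixture (a complete pipeline run on
a 20-cube glioblastoma-mode labyrinth phantom at shipped defaults) is shared
by every test that inspects a realistic trajectory set, so the expensive
walk happens once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import invasionmap as im


@pytest.fixture(scope="session")
def corridor_bundle():
    """Noiseless straight 1-wide corridor ending at a spherical tumor."""
    spec = im.PhantomSpec(
        grid_shape=(24, 9, 9), geometry="corridor", tumor_radius=2.0,
        edema_radius=2.0, noise_sigma=0.0, seed=11,
    )
    return im.make_phantom(spec)


@pytest.fixture(scope="session")
def corridor_dm(corridor_bundle):
    return im.compute_distance_map(corridor_bundle.wm, corridor_bundle.tumor)


@pytest.fixture(scope="session")
def gbm_bundle():
    """20-cube glioblastoma-mode labyrinth phantom (the study conditions:
    map_contrast = 10 x noise_sigma, gradient_extent 5)."""
    return im.make_phantom(im.PhantomSpec(grid_shape=(20, 20, 20), seed=3))


@pytest.fixture(scope="session")
def gbm_run(gbm_bundle):
    """Full default-configuration pipeline run on the glioblastoma phantom."""
    b = gbm_bundle
    return im.run_pipeline(b.wm, b.tumor, b.tensors, b.pmap,
                           im.WalkConfig(seed=5))


@pytest.fixture(scope="session")
def metastasis_run():
    """Same geometry, metastasis mode: nothing planted outside the tumor."""
    b = im.make_phantom(im.PhantomSpec(grid_shape=(20, 20, 20), seed=3,
                                       mode="metastasis"))
    return b, im.run_pipeline(b.wm, b.tumor, b.tensors, b.pmap,
                              im.WalkConfig(seed=5))


def brute_force_distance(wm_vals: np.ndarray, tumor_vals: np.ndarray,
                         connectivity: int = 26) -> np.ndarray:
    """Independent oracle: unit-weight shortest-path search on the voxel
    adjacency graph (scipy.sparse.csgraph Dijkstra from the tumor-adjacent
    seed set).  Returns an int32 volume with -1 for unreachable voxels."""
    from itertools import product

    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    shape = wm_vals.shape
    wm_vals = wm_vals & ~tumor_vals
    idx = np.argwhere(wm_vals)
    flat = np.ravel_multi_index(idx.T, shape)
    pos = {f: n for n, f in enumerate(flat)}
    offsets = [o for o in product((-1, 0, 1), repeat=3) if any(o)]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    rows, cols = [], []
    seeds = set()
    for o in offsets:
        nb = idx + o
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_flat = np.ravel_multi_index(nb[ok].T, shape)
        for a, bflat, nijk in zip(np.flatnonzero(ok), nb_flat, nb[ok]):
            if bflat in pos:
                rows.append(a)
                cols.append(pos[bflat])
            if tumor_vals[tuple(nijk)]:
                seeds.add(a)
    d = np.full(shape, -1, dtype=np.int32)
    if not seeds:
        return d
    n = len(flat)
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    dist = dijkstra(g, indices=sorted(seeds), unweighted=True, min_only=True)
    reach = np.isfinite(dist)
    d.reshape(-1)[flat[reach]] = dist[reach].astype(np.int32) + 1
    return d
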