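"""Pseudorandom trajectory generation over the white-matter lattice.

A trajectory is a voxel-lattice random walk whose step probabilities are the
gated, ADC-weighted transition rows (see :mod:`invasionmap.transitions`).
The *toward* segment walks from a start voxel down the distance map until it
enters a voxel at step distance 1 (the tumor margin); the *away* segment
walks outward from the same start under the opposite gating.  For starts not
at the maximal distance the full trajectory is stitched: reversed away
segment + toward segment — one continuous path from far white matter to the
tumor border.

Stall limiting: a walk may wander along an isodistance shell (equal-distance
neighbors are admissible).  After ``stall_limit`` consecutive steps at
unchanged distance (default 12) a toward-walk restricts its next draw to the
strictly-descending neighbors (renormalized); an away-walk simply stops.

Scheduling (coverage-driven): start points are taken per distance stratum
from the outermost distance inward.  In the first cycle starts are drawn
uniformly among voxels no trajectory has visited yet; in later cycles, among
the stratum's minimal-coverage voxels — until every eligible voxel has been
visited by at least ``min_coverage`` trajectories (default 100).  A
trajectory counts at most once per distinct voxel it visits.

Reproducibility: a single seeded :class:`numpy.random.Generator` drives, in
fixed order per trajectory, (1) the start-voxel draw, (2) the toward-walk
stream seed, (3) the away-walk stream seed; the step draws themselves come
from a splitmix64 counter stream inside the compiled kernel.  Identical
seeds give bit-identical trajectory sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core_io import VoxelGrid
from .distance import UNREACHABLE, DistanceMap
from .transitions import TransitionWeights

__all__ = [
    "WalkConfig",
    "Trajectory",
    "CoverageCounter",
    "TrajectoryEngine",
    "walk_toward_tumor",
    "walk_away_from_tumor",
    "generate_trajectory_set",
]


@dataclass(frozen=True)
class WalkConfig:
    """Walk and scheduler settings; the defaults are the method's own.

    min_coverage : trajectories required through every eligible voxel (100).
    stall_limit : consecutive equal-distance steps tolerated before a
        toward-walk is forced to descend / an away-walk stops (12).
    seed : master seed for the whole run.
    max_cycles : safety bound on scheduler cycles (pathological geometry).
    """

    min_coverage: int = 100
    stall_limit: int = 12
    seed: int = 0
    max_cycles: int = 1000

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.stall_limit < 1 or self.max_cycles < 1:
            raise ValueError("min_coverage, stall_limit and max_cycles must be positive")


@dataclass
class Trajectory:
    """An ordered voxel path with its distance sequence.

    ``voxels`` are flat volume indices (row-major); ``distances`` the
    matching step distances.  Order runs from the far end toward the tumor:
    the distance sequence is non-increasing.  ``reached_margin`` is True
    when the final voxel has d = 1; ``stitched`` when the path was assembled
    from an away segment and a toward segment sharing ``start``.
    """

    voxels: np.ndarray
    distances: np.ndarray
    start: int
    reached_margin: bool
    stitched: bool

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class CoverageCounter:
    """Per-voxel count of trajectories that visited the voxel (distinct visits)."""

    grid: VoxelGrid
    counts: np.ndarray      # int32 volume; 0 outside the eligible set
    eligible: np.ndarray    # boolean volume

    @property
    def min_eligible(self) -> int:
        return int(self.counts[self.eligible].min())


# ---------------------------------------------------------------------------
# Compiled walk kernels.  splitmix64 gives a tiny, well-mixed counter RNG
# whose state is a single uint64, cheap to seed per trajectory.

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _sm64(state):
    state = state + _SM_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    z = z ^ (z >> np.uint64(31))
    return state, (z >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def _kernel_toward(start, cum_w, cum_desc, nbr, d_row, stall_limit, seed, path):
    """Walk down the distance map; returns (n_steps, reached_flag).

    reached_flag 0 marks a failed segment (no admissible move before the
    margin, or the path buffer overflowed).
    """
    state = np.uint64(seed)
    cur = start
    path[0] = cur
    n = 1
    stall = 0
    max_steps = path.shape[0]
    while d_row[cur] > 1:
        if stall >= stall_limit:
            row = cum_desc[cur]
        else:
            row = cum_w[cur]
        tot = row[25]
        if tot <= 0.0:
            return n, 0
        state, u = _sm64(state)
        r = u * tot
        k = 0
        while k < 25 and row[k] <= r:
            k += 1
        nxt = nbr[cur, k]
        if d_row[nxt] == d_row[cur]:
            stall += 1
        else:
            stall = 0
        cur = nxt
        if n >= max_steps:
            return n, 0
        path[n] = cur
        n += 1
    return n, 1


@njit(cache=True)
def _kernel_away(start, cum_w, nbr, d_row, stall_limit, seed, path):
    """Walk up the distance map until a local maximum or the stall limit."""
    state = np.uint64(seed)
    cur = start
    path[0] = cur
    n = 1
    stall = 0
    max_steps = path.shape[0]
    while True:
        row = cum_w[cur]
        tot = row[25]
        if tot <= 0.0 or stall >= stall_limit or n >= max_steps:
            return n
        state, u = _sm64(state)
        r = u * tot
        k = 0
        while k < 25 and row[k] <= r:
            k += 1
        nxt = nbr[cur, k]
        if d_row[nxt] == d_row[cur]:
            stall += 1
        else:
            stall = 0
        cur = nxt
        path[n] = cur
        n += 1


# ---------------------------------------------------------------------------


class TrajectoryEngine:
    """Precomputed walk arrays plus the coverage-driven scheduler.

    Builds cumulative-weight rows for the toward matrix, its
    strictly-descending restriction (used after a stall), and the away
    matrix, all in the eligible-row index space of the transition matrices.
    """

    def __init__(self, tw_toward: TransitionWeights, tw_away: TransitionWeights,
                 dm: DistanceMap, cfg: WalkConfig):
        if tw_toward.mode != "toward_tumor" or tw_away.mode != "away_from_tumor":
            raise ValueError("engine needs one toward-tumor and one away-from-tumor matrix")
        if not np.array_equal(tw_toward.elig_flat, tw_away.elig_flat):
            raise ValueError("transition matrices disagree on the eligible set")
        self.dm = dm
        self.cfg = cfg
        self.elig_flat = tw_toward.elig_flat
        self.vol_to_row = tw_toward.vol_to_row
        self.nbr_toward = tw_toward.neighbor_row
        self.nbr_away = tw_away.neighbor_row
        self.d_row = dm.d.reshape(-1)[self.elig_flat].astype(np.int32)

        self.cum_toward = np.cumsum(tw_toward.W, axis=1)
        self.cum_away = np.cumsum(tw_away.W, axis=1)
        # Strictly-descending restriction of the toward rows (stall recovery).
        d_nb = np.where(self.nbr_toward >= 0, self.d_row[self.nbr_toward], -1)
        desc = tw_toward.W * (d_nb == (self.d_row[:, None] - 1))
        self.cum_desc = np.cumsum(desc, axis=1)

        # Path buffer: a walk descends at most d_max times and makes at most
        # stall_limit lateral steps between descents.
        self._buf_len = int((dm.d_max + 2) * (cfg.stall_limit + 1) + 4)
        self._buf = np.empty(self._buf_len, dtype=np.int32)
        self.failed_segments = 0

    # -- single walks -------------------------------------------------------

    def toward_segment(self, start_row: int, seed: int) -> tuple[np.ndarray, bool]:
        """Row path of a toward-walk and whether it reached the margin."""
        n, ok = _kernel_toward(
            np.int64(start_row), self.cum_toward, self.cum_desc, self.nbr_toward,
            self.d_row, np.int64(self.cfg.stall_limit), np.uint64(seed), self._buf,
        )
        return self._buf[:n].copy(), bool(ok)

    def away_segment(self, start_row: int, seed: int) -> np.ndarray:
        n = _kernel_away(
            np.int64(start_row), self.cum_away, self.nbr_away,
            self.d_row, np.int64(self.cfg.stall_limit), np.uint64(seed), self._buf,
        )
        return self._buf[:n].copy()

    def _to_trajectory(self, rows: np.ndarray, start_row: int,
                       reached: bool, stitched: bool) -> Trajectory:
        return Trajectory(
            voxels=self.elig_flat[rows].astype(np.int64),
            distances=self.d_row[rows].astype(np.int32),
            start=int(self.elig_flat[start_row]),
            reached_margin=reached,
            stitched=stitched,
        )

    def build_one(self, start_row: int, rng: np.random.Generator,
                  *, stitch: bool, max_retries: int = 100) -> Trajectory:
        """One complete trajectory from a start row; failed toward segments
        are discarded and redrawn (they are not counted anywhere)."""
        for _ in range(max_retries):
            toward, ok = self.toward_segment(start_row, int(rng.integers(1, 2**31)))
            if stitch:
                away = self.away_segment(start_row, int(rng.integers(1, 2**31)))
            if ok:
                if stitch and len(away) > 1:
                    rows = np.concatenate([away[::-1][:-1], toward])
                    return self._to_trajectory(rows, start_row, True, True)
                return self._to_trajectory(toward, start_row, True, stitch)
            self.failed_segments += 1
        raise RuntimeError(
            f"toward-walk from row {start_row} failed {max_retries} times; "
            "the transition matrix has a dead end"
        )

    # -- scheduler ----------------------------------------------------------

    def generate(self) -> tuple[list[Trajectory], CoverageCounter]:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        d_max = self.dm.d_max
        strata = {d: np.flatnonzero(self.d_row == d) for d in range(1, d_max + 1)}
        coverage = np.zeros(len(self.elig_flat), dtype=np.int32)
        trajectories: list[Trajectory] = []

        def launch(start_row: int) -> None:
            traj = self.build_one(start_row, rng,
                                  stitch=self.d_row[start_row] < d_max)
            rows = self.vol_to_row[traj.voxels]
            coverage[np.unique(rows)] += 1
            trajectories.append(traj)

        done = False
        for cycle in range(cfg.max_cycles):
            for dist in range(d_max, 0, -1):
                stratum = strata[dist]
                if stratum.size == 0:
                    continue
                while True:
                    cov = coverage[stratum]
                    if cycle == 0:
                        cand = stratum[cov == 0]
                        if cand.size == 0:
                            break
                    else:
                        lo = cov.min()
                        if lo >= cfg.min_coverage:
                            break
                        cand = stratum[cov == lo]
                    launch(int(cand[rng.integers(cand.size)]))
            if coverage.min() >= cfg.min_coverage:
                done = True
                break
        if not done:
            raise RuntimeError(
                f"scheduler did not reach coverage {cfg.min_coverage} within "
                f"{cfg.max_cycles} cycles"
            )

        counts = np.zeros(self.dm.grid.n_voxels, dtype=np.int32)
        counts[self.elig_flat] = coverage
        counter = CoverageCounter(
            grid=self.dm.grid,
            counts=counts.reshape(self.dm.grid.shape),
            eligible=(self.dm.d != UNREACHABLE),
        )
        return trajectories, counter


# ---------------------------------------------------------------------------
# Functional interface.

def _row_of(tw: TransitionWeights, start) -> int:
    start = np.asarray(start)
    if start.ndim == 0:
        row = int(tw.vol_to_row[int(start)])
        if row < 0:
            raise ValueError(f"start voxel (flat {int(start)}) is not eligible")
        return row
    return tw.row_of_voxel(start)


def walk_toward_tumor(start, tw_toward: TransitionWeights, dm: DistanceMap,
                      cfg: WalkConfig, rng: np.random.Generator) -> Trajectory:
    """One toward-tumor segment from a start voxel (``(i,j,k)`` or flat index).

    ``reached_margin`` is False for a failed segment (no admissible move
    before the margin); failed segments carry the partial path.
    """
    eng = _single_mode_engine(tw_toward, dm, cfg)
    row = _row_of(tw_toward, start)
    rows, ok = eng.toward_segment(row, int(rng.integers(1, 2**31)))
    return eng._to_trajectory(rows, row, ok, False)


def walk_away_from_tumor(start, tw_away: TransitionWeights, dm: DistanceMap,
                         cfg: WalkConfig, rng: np.random.Generator) -> Trajectory:
    """One away-from-tumor segment; always succeeds (possibly single voxel).

    The returned path is ordered start -> outward, so its distance sequence
    is non-decreasing; ``reached_margin`` is False by construction.
    """
    eng = _single_mode_engine(tw_away, dm, cfg)
    row = _row_of(tw_away, start)
    rows = eng.away_segment(row, int(rng.integers(1, 2**31)))
    return eng._to_trajectory(rows, row, False, False)


def _single_mode_engine(tw: TransitionWeights, dm: DistanceMap,
                        cfg: WalkConfig) -> TrajectoryEngine:
    """Engine over one matrix: the missing mode is faked with a zero matrix."""
    import copy
    other = copy.copy(tw)
    other.mode = ("away_from_tumor" if tw.mode == "toward_tumor" else "toward_tumor")
    other.W = np.zeros_like(tw.W)
    if tw.mode == "toward_tumor":
        return TrajectoryEngine(tw, other, dm, cfg)
    return TrajectoryEngine(other, tw, dm, cfg)


def generate_trajectory_set(
    tw_toward: TransitionWeights,
    tw_away: TransitionWeights,
    dm: DistanceMap,
    cfg: WalkConfig,
) -> tuple[list[Trajectory], CoverageCounter]:
    """Run the full coverage-driven scheduler; see the module docstring."""
    engine = TrajectoryEngine(tw_toward, tw_away, dm, cfg)
    return engine.generate()
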