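"""Per-voxel aggregation of significant profile gradients: the 100·P/Q maps.

Every eligible voxel collects three numbers over all trajectories passing
through it: Q, the total number of trajectories through the voxel (each
trajectory counted once, however often it revisits); P_up, how many of those
trajectories carry the voxel inside a *significant rising* segment of their
profile (signal elevated toward the tumor); and P_down, the same for falling
segments.  The output maps are the percentages 100·P_up/Q and 100·P_down/Q,
NaN where no trajectory passed.  A voxel lying in both a rising and a
falling significant segment of one trajectory counts in both maps — they
are reported as two separate volumes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .core_io import BinaryMask, ScalarMap, TensorField, VoxelGrid, validate_grids
from .distance import UNREACHABLE, DistanceMap, compute_distance_map
from .profiles import (Profile, SmoothingConfig, detect_gradient_segments,
                       extract_profile, sliding_median, smooth_profile)
from .trajectories import (CoverageCounter, Trajectory, TrajectoryEngine,
                           WalkConfig, generate_trajectory_set)
from .transitions import build_transition_matrix

__all__ = [
    "VoxelGradientStats",
    "GradientMap",
    "PipelineResult",
    "accumulate_stats",
    "compute_gradient_map",
    "run_pipeline",
]


@dataclass
class VoxelGradientStats:
    """Per-voxel trajectory counts: q (total), p_up / p_down (significant)."""

    grid: VoxelGrid
    p_up: np.ndarray
    p_down: np.ndarray
    q: np.ndarray


@dataclass
class GradientMap:
    """The 100·P/Q percentage maps for one parametric map.

    ``up_pct`` marks voxels whose signal is significantly elevated toward
    the tumor along the trajectories through them; ``down_pct`` significantly
    depressed.  NaN where no trajectory passed (q = 0).
    """

    grid: VoxelGrid
    up_pct: np.ndarray
    down_pct: np.ndarray
    map_name: str = "other"


def accumulate_stats(profiles: list[Profile], dm: DistanceMap) -> VoxelGradientStats:
    """Count, per voxel, total and significantly-rising/-falling trajectories.

    Each profile must carry its segment labels.  Per profile, every distinct
    voxel increments q once; it increments p_up when any of its samples lies
    inside a significant rising segment (inclusive endpoints), and p_down
    likewise for falling segments.
    """
    nvox = dm.grid.n_voxels
    q = np.zeros(nvox, dtype=np.int32)
    p_up = np.zeros(nvox, dtype=np.int32)
    p_down = np.zeros(nvox, dtype=np.int32)
    for p in profiles:
        if p.segments is None:
            raise ValueError("profile has no segment labels; run detection first")
        _accumulate_one(p, q, p_up, p_down)
    shape = dm.grid.shape
    return VoxelGradientStats(grid=dm.grid, q=q.reshape(shape),
                              p_up=p_up.reshape(shape), p_down=p_down.reshape(shape))


def _accumulate_one(p: Profile, q: np.ndarray, p_up: np.ndarray,
                    p_down: np.ndarray) -> None:
    vox = p.voxel_of_sample
    np.add.at(q, np.unique(vox), 1)
    n = len(vox)
    for direction, acc in (("rising", p_up), ("falling", p_down)):
        mask = np.zeros(n, dtype=bool)
        for seg in p.segments:
            if seg.significant and seg.direction == direction:
                mask[seg.start_sample:seg.end_sample + 1] = True
        if mask.any():
            np.add.at(acc, np.unique(vox[mask]), 1)


def compute_gradient_map(stats: VoxelGradientStats, map_name: str = "other"
                         ) -> GradientMap:
    """Elementwise 100·p/q, NaN where q = 0, for rising and falling counts."""
    with np.errstate(invalid="ignore", divide="ignore"):
        q = stats.q.astype(np.float64)
        up = np.where(stats.q > 0, 100.0 * stats.p_up / q, np.nan)
        down = np.where(stats.q > 0, 100.0 * stats.p_down / q, np.nan)
    return GradientMap(grid=stats.grid, up_pct=up, down_pct=down, map_name=map_name)


@dataclass
class PipelineResult:
    """Everything a full run produces, for export and inspection."""

    distance_map: DistanceMap
    coverage: CoverageCounter
    trajectories: list[Trajectory]
    gradient_maps: list[GradientMap]
    stats: list[VoxelGradientStats]
    failed_segments: int
    wall_time_s: float


def run_pipeline(
    wm: BinaryMask,
    tumor: BinaryMask,
    tensors: TensorField,
    pmaps: list[ScalarMap] | ScalarMap,
    walk_cfg: WalkConfig = WalkConfig(),
    smooth_cfg: SmoothingConfig = SmoothingConfig(),
    *,
    progress: bool = False,
) -> PipelineResult:
    """Run all stages: distance map, transition matrices, one trajectory set,
    then — per parametric map — profiles, segmentation, and the 100·P/Q maps.

    The geometric stages run once; the identical trajectory set is reused
    for every parametric map, so all output maps are directly comparable.
    """
    t0 = time.perf_counter()
    if isinstance(pmaps, ScalarMap):
        pmaps = [pmaps]
    validate_grids([wm, tumor, tensors, *pmaps])

    dm = compute_distance_map(wm, tumor)
    tw_toward = build_transition_matrix(tensors, dm, "toward_tumor")
    tw_away = build_transition_matrix(tensors, dm, "away_from_tumor")
    engine = TrajectoryEngine(tw_toward, tw_away, dm, walk_cfg)
    trajectories, coverage = engine.generate()

    maps: list[GradientMap] = []
    all_stats: list[VoxelGradientStats] = []
    for pmap in pmaps:
        profiles_iter = _profiles_with_segments(trajectories, pmap, dm, smooth_cfg)
        stats = _accumulate_streaming(profiles_iter, dm)
        all_stats.append(stats)
        maps.append(compute_gradient_map(stats, map_name=pmap.name))
    return PipelineResult(
        distance_map=dm, coverage=coverage, trajectories=trajectories,
        gradient_maps=maps, stats=all_stats,
        failed_segments=engine.failed_segments,
        wall_time_s=time.perf_counter() - t0,
    )


def _profiles_with_segments(trajectories, pmap, dm, smooth_cfg):
    pvals = pmap.values.reshape(-1)
    for tid, traj in enumerate(trajectories):
        vox = traj.voxels[::-1]
        raw = pvals[vox]
        p = Profile(trajectory_id=tid, x=traj.distances[::-1], raw=raw,
                    voxel_of_sample=vox)
        p.smoothed = sliding_median(raw, smooth_cfg.filter_order)
        detect_gradient_segments(p, smooth_cfg)
        yield p


def _accumulate_streaming(profiles_iter, dm: DistanceMap) -> VoxelGradientStats:
    nvox = dm.grid.n_voxels
    q = np.zeros(nvox, dtype=np.int32)
    p_up = np.zeros(nvox, dtype=np.int32)
    p_down = np.zeros(nvox, dtype=np.int32)
    for p in profiles_iter:
        _accumulate_one(p, q, p_up, p_down)
    shape = dm.grid.shape
    return VoxelGradientStats(grid=dm.grid, q=q.reshape(shape),
                              p_up=p_up.reshape(shape), p_down=p_down.reshape(shape))
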