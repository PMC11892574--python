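# Methods

## The procedure

`invasionmap` maps where a scalar MRI parameter changes significantly on the
approach to a brain-tumor border, following white-matter geometry rather than
straight lines. The pipeline has five computational stages, all confined to a
binary white-matter mask treated as a voxel "labyrinth":

1. **Step-distance map.** Every white-matter voxel is labeled with the minimal
   number of single-voxel steps (26-connected; diagonal steps count 1) to a
   voxel adjacent to the tumor. Labeling is iterative dilation from the tumor
   border: tumor-adjacent white matter gets d = 1, its unlabeled white-matter
   neighbors d = 2, and so on until no voxel can be added. White matter not
   connected to the tumor is never labeled and is excluded from all later
   stages. This is a path length through the mask, not a Euclidean distance.

2. **Transition matrices.** For each eligible voxel *i* and each of its 26
   neighbors *j*, the directional apparent diffusion coefficient is the
   tensor quadratic form ADC_ij = n_ijᵀ D_i n_ij (mm²/s, clamped at 0), with
   n_ij the unit lattice direction. Gate coefficients m_ij zero out neighbors
   outside the eligible white matter and, in *toward-tumor* mode, neighbors
   with d_j > d_i (in *away* mode, d_j < d_i — only the strict inequalities
   nullify, so equal-distance neighbors stay admissible in both modes). Step
   probabilities are W_ij = m_ij·ADC_ij / Σ_j m_ij·ADC_ij, materialized once
   as two dense n_eligible×26 matrices.

3. **Pseudorandom trajectories.** A toward-walk samples steps from the W rows
   until it enters a voxel at d = 1 (the tumor margin). An away-walk does the
   same under the away matrix until it reaches a local distance maximum
   (all-zero row) or exceeds the stall limit. Start points are scheduled per
   distance stratum from the outermost distance inward: first among
   never-visited voxels, in later passes among the stratum's minimal-coverage
   voxels, until **every** eligible voxel has been visited by at least
   `min_coverage` trajectories. Starts below the maximal distance are
   stitched: reversed away segment + toward segment, one continuous path from
   far white matter to the tumor.

4. **Profiles.** The parametric map is sampled along each trajectory and
   plotted against step distance with the tumor border at the origin. The raw
   profile is smoothed with a sliding median (window `filter_order`); the
   smoothed profile is split at its local extrema into alternating monotone
   segments, and a segment is *significant* when its amplitude exceeds a
   threshold (below).

5. **Gradient maps.** Per voxel: Q = trajectories through the voxel, P_up =
   those whose profile holds the voxel inside a significant *rising* segment,
   P_down likewise for falling. The outputs are 100·P_up/Q and 100·P_down/Q
   as two separate volumes (a voxel can carry both), NaN where Q = 0.

### Sign convention

A **rising** segment is one whose smoothed value increases *as the tumor is
approached* — i.e. the tumor-side endpoint of the monotone stretch is the
higher one. `up_pct` therefore highlights parameters elevated adjacent to and
ahead of the tumor border (the typical infiltration signature for kurtosis
metrics), `down_pct` parameters depressed toward the tumor. This is the
package's fixed convention; swapping the two maps reinterprets, not
recomputes, a run.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_coverage` | 100 | trajectories | completion rule: minimum trajectories through every eligible voxel |
| `stall_limit` | 12 | steps | consecutive equal-distance steps before a toward-walk is forced to descend / an away-walk stops |
| `filter_order` | 6 | samples | sliding-median window for profile smoothing |
| `significance_k` | 3.0 | — | multiplier on the robust per-profile noise scale |
| `absolute_threshold` | unset | map units | overrides `significance_k` for calibrated maps |
| ADC floor | 1e-6 | mm²/s | minimum directional ADC credited to an admissible neighbor |
| grid-affine tolerance | 0.01 | mm/element | co-registration agreement required of the inputs |

`min_coverage`, `stall_limit` and `filter_order` are the method's own
constants and ship as the out-of-box configuration. The significance
threshold is `significance_k × 1.4826 × median(|raw − smoothed|)`, the
normal-consistent MAD of the smoothing residual computed per profile, which
makes the test scale-free across parametric maps with different units
(multiplying a map by a positive constant changes neither output map). With
k = 3 and window 6, Monte-Carlo on iid-noise profiles gives a per-profile
false-positive rate of roughly 7–8% (a significant segment somewhere in the
profile); per-voxel false-positive percentages on a structure-free phantom
come out near 3–5%. Raise `significance_k` or set `absolute_threshold` for
stricter maps.

## Numerical choices

- **Adjacency** is the full 26-neighborhood for both the distance labeling
  and the transitions, so "one voxel per step" means the same thing in both
  stages; 6- or 18-connected labeling is available as an option.
- **ADC floor.** Noisy tensors can make every gated directional ADC zero,
  which would create dead ends the walk model forbids. Admissible neighbors
  are credited at least 1e-6 mm²/s — three orders of magnitude below healthy
  white-matter diffusivity (~1e-3 mm²/s) — before normalization, so rows are
  all-zero only when *no* admissible neighbor exists.
- **Stall recovery.** After `stall_limit` equal-distance steps a toward-walk
  draws its next step from the strictly-descending neighbors only
  (renormalized); the distance-map invariant guarantees such a neighbor
  exists for every voxel with d > 1, so toward-walks cannot be trapped.
- **Median filter.** "Window 6" is an even-length sliding window; the even
  median is the mean of the two central order statistics, and windows are
  clipped at the profile ends (a length-3 profile is smoothed by the median
  of all three samples). Smoothing runs over the sample sequence, not over
  unique distances, so equal-distance wandering samples each keep a value.
- **Extrema.** Plateaus of the smoothed profile collapse to their midpoint
  sample; the first and last sample always count as extrema so the monotone
  segments partition the whole profile. Segment endpoints are shared: an
  extremum sample belongs to both adjacent segments.
- **Counting.** A trajectory increments a voxel's Q once no matter how often
  it revisits it, and increments P_up (P_down) once when *any* of the
  voxel's samples lies inside a significant rising (falling) segment.
- **Determinism.** One seeded generator drives, in fixed order per
  trajectory, the start-voxel draw and the two walk-stream seeds; the step
  draws come from a splitmix64 counter stream inside the compiled kernel.
  Identical seed and configuration reproduce every output volume
  byte-for-byte.
- **Degenerate inputs.** Empty tumor mask, empty white matter, or no
  white-matter voxel adjacent to the tumor abort with a diagnostic; a
  tumor/white-matter overlap is resolved as tumor; an all-unreachable
  eligible set refuses to run.

## The synthetic phantoms

No imaging data ship with the package; phantoms generate every structural
feature the algorithm consumes. Geometries: a straight **corridor** (forced
walks, used for exact step tests), a randomized connected 3-D **labyrinth**
maze with a solid perifocal white-matter shell around a spherical tumor (the
realistic default), a solid **shell** with radial tensors, and a
**two-slice** phantom whose two planar corridor systems are joined by an
oblique bridge, so the planted gradient is invisible in any single slice but
visible along trajectories. Tensors are cigar-shaped, principal axis along
the local corridor direction (1.7e-3 / 0.3e-3 mm²/s by default, typical
healthy white matter), symmetric positive definite by construction. In
glioblastoma mode the parametric map carries a planted invasion signature —
a ramp of height `map_contrast` (default 0.3, ~10× the default noise sd
0.03, on a kurtosis-like baseline of 0.8) at the tumor border decaying
linearly over `gradient_extent` (default 5) distance steps; metastasis mode
plants nothing outside the tumor, emulating purely vasogenic edema. Additive
Gaussian noise models thermal noise on the map.

The phantoms are lattice-native: no partial-volume effects, no curved
sub-voxel fibers, no gray-matter/CSF compartments, no correlated DKI fitting
noise, and tensors are noiseless unless the perturbation knob is used.
Passing tests therefore demonstrate the correctness of the algorithmic
machinery under the planted conditions, not clinical performance on real
acquisitions.

## Problem sizes

The test suite exercises exact oracles (unit-weight shortest paths,
order-statistics medians, multinomial step laws) on grids up to 20³ and runs
the complete default-configuration pipeline on a 20³ labyrinth phantom
(~1.9k eligible voxels, ~36k trajectories). The acceptance script runs the
default 40³ labyrinth (~14k eligible voxels, ~300k trajectories) end to end
at shipped defaults. These sizes were chosen so the whole suite completes in
a few minutes on one core while every contract is still checked exhaustively.

## Known limitations

- Single-tensor diffusion model: crossing-fiber voxels steer walks by the
  averaged tensor only; no orientation-distribution models.
- Distances are step counts; anisotropic voxel sizes are not converted to
  metric path length.
- The significance test is per-profile and descriptive; the output
  percentage maps carry no multiple-comparison-corrected inference.
- Segmentation quality dominates: the algorithm consumes externally produced
  masks and is sensitive to their errors at the tumor border.
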