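"""Profile extraction, median smoothing, and gradient-segment detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import invasionmap as im
from invasionmap.profiles import (Profile, SmoothingConfig, _extremum_indices,
                                  detect_gradient_segments, noise_scale,
                                  sliding_median, smooth_profile)


def _profile(raw, x=None):
    raw = np.asarray(raw, dtype=float)
    if x is None:
        x = np.arange(1, len(raw) + 1)
    return Profile(0, np.asarray(x), raw, np.arange(len(raw)))


def brute_median(values, window):
    """Oracle: direct order-statistics evaluation of every clipped window."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    w = min(window, n)
    left = (w - 1) // 2
    right = w - 1 - left
    return np.array([np.median(values[max(0, i - left): min(n, i + right + 1)])
                     for i in range(n)])


class TestExtractProfile:
    def test_constant_map(self, corridor_bundle, corridor_dm):
        b, dm = corridor_bundle, corridor_dm
        pmap = im.ScalarMap(b.pmap.grid, np.full(dm.grid.shape, 2.5))
        toward = im.build_transition_matrix(b.tensors, dm, "toward_tumor")
        start = tuple(np.argwhere(dm.d == dm.d_max)[0])
        traj = im.walk_toward_tumor(start, toward, dm, im.WalkConfig(seed=1),
                                    np.random.default_rng(0))
        p = im.extract_profile(traj, pmap, dm)
        assert np.all(p.raw == 2.5)

    def test_distance_ramp_map_reproduces_x(self, corridor_bundle, corridor_dm):
        """pmap = d (identity ramp) makes raw equal x exactly."""
        b, dm = corridor_bundle, corridor_dm
        pmap = im.ScalarMap(b.pmap.grid, dm.d.astype(float))
        toward = im.build_transition_matrix(b.tensors, dm, "toward_tumor")
        start = tuple(np.argwhere(dm.d == dm.d_max)[0])
        traj = im.walk_toward_tumor(start, toward, dm, im.WalkConfig(seed=1),
                                    np.random.default_rng(0))
        p = im.extract_profile(traj, pmap, dm)
        np.testing.assert_array_equal(p.raw, p.x)
        assert p.x[0] == 1 and np.all(np.diff(p.x) >= 0)

    def test_stitched_orientation_tumor_first(self, gbm_run, gbm_bundle):
        dm = gbm_run.distance_map
        traj = next(t for t in gbm_run.trajectories if t.stitched)
        p = im.extract_profile(traj, gbm_bundle.pmap, dm)
        assert p.x[0] == 1
        assert np.all(np.diff(p.x) >= 0)

    def test_nonfinite_value_rejected(self, corridor_bundle, corridor_dm):
        b, dm = corridor_bundle, corridor_dm
        vals = np.full(dm.grid.shape, np.nan)
        pmap = im.ScalarMap(b.pmap.grid, vals)
        toward = im.build_transition_matrix(b.tensors, dm, "toward_tumor")
        start = tuple(np.argwhere(dm.d == 1)[0])
        traj = im.walk_toward_tumor(start, toward, dm, im.WalkConfig(seed=1),
                                    np.random.default_rng(0))
        with pytest.raises(ValueError, match="non-finite"):
            im.extract_profile(traj, pmap, dm)


class TestSlidingMedian:
    def test_constant_unchanged(self):
        np.testing.assert_array_equal(sliding_median(np.full(20, 3.0), 6),
                                      np.full(20, 3.0))

    def test_impulse_removed_from_ramp(self):
        """A single +10 spike on a linear ramp vanishes: the smoothed value
        stays within the local ramp values (order-statistics oracle)."""
        ramp = np.arange(21, dtype=float)
        spiked = ramp.copy()
        spiked[10] += 10.0
        sm = sliding_median(spiked, 6)
        window = spiked[8:14]  # the clipped window at sample 10
        assert sm[10] == np.median(window)
        assert ramp[8] <= sm[10] <= ramp[13]

    def test_short_profile_uses_largest_fitting_window(self):
        y = np.array([5.0, 1.0, 9.0])
        out = sliding_median(y, 6)
        np.testing.assert_array_equal(out, brute_median(y, 6))
        assert out[1] == 5.0  # median over all three samples

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40),
           st.integers(min_value=1, max_value=9))
    def test_matches_order_statistics_oracle(self, values, window):
        np.testing.assert_allclose(sliding_median(np.array(values), window),
                                   brute_median(values, window))

    def test_odd_window_identity_on_monotone_interior(self):
        """An odd centered window leaves a monotone interior untouched, so
        the filter is idempotent there; the even default only shifts by half
        a sample step."""
        y = np.linspace(0, 10, 30)
        np.testing.assert_allclose(sliding_median(y, 7)[3:-3], y[3:-3], atol=1e-12)
        step = y[1] - y[0]
        assert np.all(np.abs(sliding_median(y, 6)[2:-3] - y[2:-3]) <= step / 2 + 1e-12)

    def test_monotone_input_stays_monotone(self):
        rng = np.random.default_rng(11)
        y = np.sort(rng.normal(0, 3, 50))
        assert np.all(np.diff(sliding_median(y, 6)) >= 0)


class TestExtremaAndSegments:
    def test_monotone_ramp_single_rising_toward_tumor(self):
        """Values decaying with distance = elevated toward the tumor: one
        significant rising segment on a noiseless profile."""
        p = _profile(np.linspace(10, 0, 25))
        segs = detect_gradient_segments(p, SmoothingConfig())
        assert len(segs) == 1
        (seg,) = segs
        assert seg.direction == "rising" and seg.significant
        assert (seg.start_sample, seg.end_sample) == (0, 24)

    def test_monotone_increasing_is_falling_segment(self):
        p = _profile(np.linspace(0, 10, 25))
        (seg,) = detect_gradient_segments(p, SmoothingConfig())
        assert seg.direction == "falling" and seg.significant

    def test_alternating_segments_partition_profile(self):
        """Several local maxima: segments alternate and their endpoints are
        exactly the detected extrema, covering every sample."""
        x = np.linspace(0, 4 * np.pi, 120)
        p = _profile(np.sin(x) * 5)
        segs = detect_gradient_segments(p, SmoothingConfig())
        assert len(segs) >= 4
        assert segs[0].start_sample == 0 and segs[-1].end_sample == len(p) - 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_sample == b.start_sample
            assert a.direction != b.direction
        for s in segs:
            y = p.smoothed[s.start_sample:s.end_sample + 1]
            diffs = np.diff(y)
            assert np.all(diffs >= -1e-12) or np.all(diffs <= 1e-12)

    def test_plateau_collapses_to_midpoint(self):
        y = np.array([0, 1, 2, 3, 3, 3, 3, 2, 1, 0], dtype=float)
        ext = _extremum_indices(y)
        np.testing.assert_array_equal(ext, [0, 4, 9])

    def test_significance_monotone_in_k(self):
        rng = np.random.default_rng(5)
        raw = np.cumsum(rng.normal(0, 1, 200))
        counts = []
        for k in (1.0, 2.0, 3.0, 5.0, 10.0):
            p = _profile(raw)
            segs = detect_gradient_segments(p, SmoothingConfig(significance_k=k))
            counts.append(sum(s.significant for s in segs))
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))

    def test_absolute_threshold_overrides(self):
        p = _profile(np.linspace(0, 4, 30))
        segs = detect_gradient_segments(
            p, SmoothingConfig(absolute_threshold=5.0))
        assert not any(s.significant for s in segs)
        p2 = _profile(np.linspace(0, 4, 30))
        segs2 = detect_gradient_segments(
            p2, SmoothingConfig(absolute_threshold=3.0))
        assert all(s.significant for s in segs2)

    def test_scale_equivariance_of_significance(self):
        """Multiplying a profile by a positive constant changes nothing:
        the default threshold is scale-free."""
        rng = np.random.default_rng(8)
        raw = np.cumsum(rng.normal(0, 1, 150)) + rng.normal(0, 0.5, 150)
        pa = _profile(raw)
        pb = _profile(raw * 37.5)
        sa = detect_gradient_segments(pa, SmoothingConfig())
        sb = detect_gradient_segments(pb, SmoothingConfig())
        assert [(s.start_sample, s.end_sample, s.direction, s.significant)
                for s in sa] == \
               [(s.start_sample, s.end_sample, s.direction, s.significant)
                for s in sb]

    def test_pure_noise_rarely_significant(self):
        """Monte-Carlo oracle at fixed seed: iid-noise profiles produce a
        significant segment in well under 10% of cases at defaults, and the
        rate drops as the threshold multiplier k grows."""
        rng = np.random.default_rng(0)
        raws = [rng.normal(0, 1, 60) for _ in range(400)]
        rates = []
        for k in (3.0, 4.5):
            hits = 0
            for raw in raws:
                p = _profile(raw)
                segs = detect_gradient_segments(p, SmoothingConfig(significance_k=k))
                hits += any(s.significant for s in segs)
            rates.append(hits / len(raws))
        assert rates[0] < 0.10
        assert rates[1] <= rates[0]


def test_noise_scale_matches_mad_formula():
    rng = np.random.default_rng(3)
    p = _profile(rng.normal(0, 2, 100))
    smooth_profile(p, SmoothingConfig())
    expected = 1.4826 * np.median(np.abs(p.raw - p.smoothed))
    assert noise_scale(p) == pytest.approx(expected)


def test_plot_profile_returns_axes(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    p = _profile(np.sin(np.linspace(0, 10, 50)))
    detect_gradient_segments(p, SmoothingConfig())
    ax = im.profiles.plot_profile(p, title="demo")
    assert ax.get_xlabel().startswith("distance")
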