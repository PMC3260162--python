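"""Histogram features: modes, bound pairs, subpopulations, colormaps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coultertrace import (
    ConfigError,
    assign_subpopulations,
    bound_pair,
    build_histogram,
    colormap_matrix,
    find_subpopulation_modes,
    generate_timecourse,
    track_modes,
)
from coultertrace.features import VolumeHistogram
from coultertrace.simulate import PopulationSpec, SimulationConfig


def hist_from_counts(counts, midpoints):
    """Histogram with given raw counts at given midpoints, no smoothing."""
    midpoints = np.asarray(midpoints, dtype=float)
    width = midpoints[1] - midpoints[0]
    edges = np.concatenate([midpoints - width / 2, [midpoints[-1] + width / 2]])
    counts = np.asarray(counts)
    return VolumeHistogram(
        bin_edges=edges,
        counts=counts,
        smoothed_counts=counts.astype(float),
        data_min=float(midpoints[0]),
        data_max=float(midpoints[-1]),
    )


def brute_force_bound_pair(hist, level):
    """Independent oracle: scan every midpoint pair outward from the mode
    for the first crossing of the target level, interpolating linearly."""
    y = hist.smoothed_counts
    x = hist.midpoints
    i0 = int(np.argmax(y))
    target = level / 100.0 * y[i0]

    def scan(direction):
        i = i0
        while 0 <= i + direction < y.size:
            j = i + direction
            if y[j] == target:
                return x[j], False
            if y[j] < target:
                t = (y[i] - target) / (y[i] - y[j])
                return x[i] + t * (x[j] - x[i]), False
            i = j
        return (hist.data_min if direction < 0 else hist.data_max), True

    lo, lo_c = scan(-1)
    hi, hi_c = scan(+1)
    return lo, hi, lo_c, hi_c


class TestBuildHistogram:
    def test_single_event(self):
        h = build_histogram(np.array([42.0]), bins=16, smoothing_bins=0)
        assert (h.counts > 0).sum() == 1
        assert h.mode_volume == pytest.approx(42.0, rel=0.05)

    def test_tie_breaks_to_lowest_volume(self):
        h = hist_from_counts([3, 3, 3, 3], [10, 20, 30, 40])
        assert h.mode_volume == 10.0

    def test_counts_sum_to_events(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(np.log(30), 0.2, 5000)
        h = build_histogram(v)
        assert h.counts.sum() == 5000

    def test_lognormal_mode_recovered(self):
        # linear bins so the count maximum estimates the density mode
        # exp(mu - sigma^2); log bins would instead target exp(mu)
        rng = np.random.default_rng(7)
        mu, sigma = np.log(40.0), 0.25
        v = rng.lognormal(mu, sigma, 10_000)
        h = build_histogram(v, bins=64, binning="linear")
        analytic_mode = np.exp(mu - sigma**2)
        bin_width = np.diff(h.bin_edges)[
            np.searchsorted(h.bin_edges, analytic_mode) - 1
        ]
        assert abs(h.mode_volume - analytic_mode) <= bin_width

    def test_zero_events_rejected(self):
        with pytest.raises(ConfigError):
            build_histogram(np.array([]))


class TestBoundPair:
    def test_worked_example(self):
        h = hist_from_counts([5, 25, 60, 100, 55, 30, 10], np.arange(10, 71, 10))
        bp = bound_pair(h, 25)
        assert bp.lower == pytest.approx(20.0)
        assert bp.upper == pytest.approx(62.5)

    def test_level_100_is_mode(self):
        h = hist_from_counts([5, 25, 60, 100, 55, 30, 10], np.arange(10, 71, 10))
        bp = bound_pair(h, 100)
        assert bp.lower == bp.upper == 40.0

    def test_unimodal_brackets_mode(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(np.log(30), 0.2, 20_000)
        h = build_histogram(v)
        for level in (10, 25, 33, 50, 90):
            bp = bound_pair(h, level)
            assert bp.lower <= h.mode_volume <= bp.upper

    def test_no_crossing_clamps_to_extremum(self):
        h = hist_from_counts([90, 100, 95], [10, 20, 30])
        bp = bound_pair(h, 50)
        assert bp.lower_clamped and bp.upper_clamped
        assert bp.lower == h.data_min and bp.upper == h.data_max

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        nbins=st.integers(3, 40),
        level=st.floats(1.0, 99.0),
    )
    def test_matches_brute_force_scan(self, seed, nbins, level):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 1000, size=nbins)
        counts[rng.integers(nbins)] += 1000  # ensure a nonzero mode
        h = hist_from_counts(counts, 10.0 + 10.0 * np.arange(nbins))
        bp = bound_pair(h, level)
        lo, hi, lo_c, hi_c = brute_force_bound_pair(h, level)
        assert bp.lower == pytest.approx(lo)
        assert bp.upper == pytest.approx(hi)
        assert (bp.lower_clamped, bp.upper_clamped) == (lo_c, hi_c)


class TestSubpopulations:
    def bimodal_sample(self, seed=0, n=30_000, w=0.5, m1=20.0, m2=80.0, sig=0.15):
        rng = np.random.default_rng(seed)
        n1 = rng.binomial(n, w)
        v = np.concatenate(
            [
                rng.lognormal(np.log(m1), sig, n1),
                rng.lognormal(np.log(m2), sig, n - n1),
            ]
        )
        return v

    def test_unimodal_single_peak(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(np.log(30), 0.2, 10_000)
        h = build_histogram(v)
        peaks = find_subpopulation_modes(h)
        assert peaks.size == 1
        assert peaks[0] == h.mode_volume

    def test_two_component_modes_recovered(self):
        v = self.bimodal_sample()
        h = build_histogram(v, bins=128)
        peaks = find_subpopulation_modes(h)
        assert peaks.size == 2
        sig = 0.15
        for peak, m in zip(peaks, (20.0, 80.0)):
            analytic = m * np.exp(-(sig**2))
            width = np.diff(h.bin_edges).max()
            assert abs(peak - analytic) <= 2 * width

    def test_close_peaks_merge(self):
        h = hist_from_counts([1, 100, 90, 100, 1], [10, 20, 30, 40, 50])
        peaks = find_subpopulation_modes(h, min_separation_bins=4)
        assert peaks.size == 1

    def test_one_peak_single_track_fraction_one(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(np.log(30), 0.2, 5000)
        h = build_histogram(v)
        labels, fracs = assign_subpopulations(v, h, find_subpopulation_modes(h))
        assert np.all(labels == 0)
        assert fracs.tolist() == [1.0]

    def test_equal_mixture_fractions_half(self):
        v = self.bimodal_sample(seed=5)
        h = build_histogram(v, bins=128)
        peaks = find_subpopulation_modes(h)
        _, fracs = assign_subpopulations(v, h, peaks)
        assert fracs.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(fracs, [0.5, 0.5], atol=0.02)

    def test_boundary_event_goes_to_lower_track(self):
        from coultertrace.features import subpopulation_boundaries

        v = self.bimodal_sample(seed=6)
        h = build_histogram(v, bins=128)
        peaks = find_subpopulation_modes(h)
        boundary = subpopulation_boundaries(h, peaks)[0]
        labels, _ = assign_subpopulations(np.array([boundary]), h, peaks)
        assert labels[0] == 0


class TestTrackModes:
    def test_stationary_peak_one_track(self):
        tracks = track_modes([np.array([40.0])] * 6)
        assert len(tracks) == 1
        assert tracks[0].mode_volumes == [40.0] * 6

    def test_split_starts_new_track(self):
        per_file = [
            np.array([40.0]),
            np.array([41.0]),
            np.array([42.0, 60.0]),
            np.array([43.0, 63.0]),
        ]
        tracks = track_modes(per_file)
        assert len(tracks) == 2
        assert tracks[0].mode_volumes == [40.0, 41.0, 42.0, 43.0]
        assert tracks[1].file_indices == [2, 3]

    def test_single_file_one_track_per_peak(self):
        tracks = track_modes([np.array([20.0, 50.0])])
        assert len(tracks) == 2
        assert all(len(t.mode_volumes) == 1 for t in tracks)

    def test_jump_limit_blocks_match(self):
        tracks = track_modes([np.array([40.0]), np.array([60.0])])
        assert len(tracks) == 2  # 50% jump exceeds the 15% default

    def test_simulated_divergence_tracked(self):
        """Two populations whose means diverge yield two tracks following
        the true component modes."""
        cfg = SimulationConfig(
            populations=[
                PopulationSpec(0.5, 30.0, 0.08, "linear", 0.0, "A"),
                PopulationSpec(0.5, 45.0, 0.08, "linear", 0.6, "B"),
            ],
            total_duration_min=30.0,
            pulses_per_file=4000,
            measurement_cv=0.005,
            seed=11,
        )
        files, truth = generate_timecourse(cfg)
        from coultertrace import timecourse_from_files
        from coultertrace.pipeline import (
            decode_file_events,
            filter_noise_floor,
            included_volumes,
        )

        tc = timecourse_from_files(files)
        per_file = []
        for i, mf in enumerate(tc):
            ev = filter_noise_floor(decode_file_events(mf, i, tc.epoch_s))
            h = build_histogram(included_volumes(ev), bins=128)
            per_file.append(find_subpopulation_modes(h, min_separation_bins=5))
        tracks = track_modes(per_file)
        long_tracks = [t for t in tracks if len(t.mode_volumes) >= len(files) - 1]
        assert len(long_tracks) == 2
        sig2 = 0.08**2
        # slower component stays near its analytic mode; faster one grows
        assert long_tracks[0].mode_volumes[-1] == pytest.approx(
            30.0 * np.exp(-sig2), rel=0.1
        )
        assert long_tracks[1].mode_volumes[-1] > long_tracks[1].mode_volumes[0]


class TestColormap:
    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(0, 600, 5000)
        v = rng.lognormal(np.log(30), 0.2, 5000)
        cm = colormap_matrix(t, v, np.arange(0, 601, 150), np.linspace(5, 100, 33))
        sums = cm.values.sum(axis=0)
        np.testing.assert_allclose(sums[sums > 0], 1.0)

    def test_single_event_single_cell(self):
        cm = colormap_matrix(
            np.array([10.0]), np.array([30.0]), [0, 150], [20, 40]
        )
        assert cm.values.sum() == 1.0
        assert cm.values.max() == 1.0

    def test_empty_column_all_zero(self):
        cm = colormap_matrix(
            np.array([10.0]), np.array([30.0]), [0, 150, 300], [20, 40]
        )
        assert cm.values[:, 1].sum() == 0.0

    def test_column_matches_histogram_on_slice(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(0, 300, 4000)
        v = rng.lognormal(np.log(30), 0.2, 4000)
        v_edges = np.linspace(5, 120, 41)
        cm = colormap_matrix(t, v, [0, 150, 300], v_edges)
        sl = v[(t >= 0) & (t < 150)]
        h = build_histogram(sl, bins=v_edges, smoothing_bins=0)
        col_counts = cm.values[:, 0] * sl[(sl >= 5) & (sl <= 120)].size
        np.testing.assert_allclose(col_counts, h.counts)


def test_widening_distribution_bound_width_grows():
    """For a population whose spread grows in time, the bound-pair width is
    non-decreasing in time within sampling error."""
    # two components whose means diverge => the mixture's spread widens
    cfg = SimulationConfig(
        populations=[
            PopulationSpec(0.5, 30.0, 0.10, "linear", 0.0, "slow"),
            PopulationSpec(0.5, 30.0, 0.10, "linear", 0.5, "fast"),
        ],
        total_duration_min=40.0,
        pulses_per_file=5000,
        seed=21,
    )
    files, _ = generate_timecourse(cfg)
    from coultertrace import timecourse_from_files
    from coultertrace.pipeline import (
        decode_file_events,
        filter_noise_floor,
        included_volumes,
    )

    tc = timecourse_from_files(files)
    widths = []
    for i, mf in enumerate(tc):
        ev = filter_noise_floor(decode_file_events(mf, i, tc.epoch_s))
        h = build_histogram(included_volumes(ev))
        widths.append(bound_pair(h, 25).width)
    # compare first vs last thirds to absorb sampling noise
    third = len(widths) // 3
    assert np.mean(widths[-third:]) > np.mean(widths[:third])
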