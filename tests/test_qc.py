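"""Debris detection and interpolation."""

import numpy as np
import pytest

from coultertrace import (
    DebrisConfig,
    QCAbortError,
    clean_timecourse,
    debris_flags_from_bounds,
    detect_debris_files,
    generate_timecourse,
    interpolate_file,
    timecourse_from_files,
)
from coultertrace.errors import ConfigError, ConsistencyError
from coultertrace.pipeline import decode_file_events, included_volumes
from coultertrace.simulate import DebrisSpec, PopulationSpec, SimulationConfig


def lognormal_files(seed=0, n_files=5, n=20_000, mean=40.0, sig=0.15):
    rng = np.random.default_rng(seed)
    return [rng.lognormal(np.log(mean), sig, n) for _ in range(n_files)]


class TestDetection:
    def test_flagged_when_exceeding_both_neighbors(self):
        flags = debris_flags_from_bounds(np.array([40.0, 41.5, 40.2]))
        # ratios 1.0375 and ~1.0323, both above 1.025
        assert flags.tolist() == [False, True, False]

    def test_not_flagged_below_threshold(self):
        flags = debris_flags_from_bounds(np.array([40.0, 40.8, 40.6]))
        # ratios 1.020 and ~1.005
        assert flags.tolist() == [False, False, False]

    def test_constant_bounds_nothing_flagged(self):
        assert not debris_flags_from_bounds(np.full(10, 40.0)).any()

    def test_edges_never_flagged(self):
        flags = debris_flags_from_bounds(np.array([100.0, 1.0, 1.0, 1.0, 100.0]))
        assert not flags[0] and not flags[-1]

    def test_either_rule_flags_one_sided_spikes(self):
        bounds = np.array([40.0, 41.5, 41.5])  # exceeds prev only
        assert not debris_flags_from_bounds(bounds, DebrisConfig()).any()
        either = DebrisConfig(neighbor_rule="either")
        assert debris_flags_from_bounds(bounds, either)[1]

    def test_fewer_than_three_files_rejected(self):
        with pytest.raises(ConsistencyError):
            debris_flags_from_bounds(np.array([1.0, 1.0]))

    def test_transition_exactly_at_threshold(self):
        vols = lognormal_files(n_files=1)[0]
        for r, expected in [(1.024, False), (1.025, True), (1.026, True)]:
            report = detect_debris_files([vols, r * vols, vols])
            assert bool(report.flagged[1]) is expected

    def test_injected_debris_file_detected(self):
        cfg = SimulationConfig(
            populations=[PopulationSpec(1.0, 40.0, 0.15, "none", 0.0)],
            total_duration_min=20.0,
            pulses_per_file=10_000,
            debris_events=[DebrisSpec(file_index=3, inflation=0.05)],
            seed=9,
        )
        files, _ = generate_timecourse(cfg)
        report = detect_debris_files(timecourse_from_files(files))
        assert report.flagged.tolist() == [False] * 3 + [True] + [False] * 2

    def test_threshold_sandwich(self):
        """A >2.5% single-file bound shift is flagged; a <=1.5% shift is not."""
        vols = lognormal_files(n_files=1, n=50_000)[0]
        big = detect_debris_files([vols, 1.04 * vols, vols])
        small = detect_debris_files([vols, 1.015 * vols, vols])
        assert bool(big.flagged[1]) and not small.flagged.any()


class TestInterpolation:
    def _neighbors(self, seed=0, n=5000, mean=40.0):
        cfg = SimulationConfig(
            populations=[PopulationSpec(1.0, mean, 0.12, "none", 0.0)],
            total_duration_min=10.0,
            pulses_per_file=n,
            seed=seed,
        )
        files, _ = generate_timecourse(cfg)
        return files

    def test_identity_on_identical_neighbors(self):
        from coultertrace import FilterConfig
        from coultertrace.pipeline import filter_noise_floor

        files = self._neighbors()
        interp = interpolate_file(files[0], files[0])
        v_out = np.sort(included_volumes(decode_file_events(interp)))
        # compare against the same included (noise-filtered) sample the
        # interpolation draws its quantiles from
        nb = filter_noise_floor(decode_file_events(files[0]), FilterConfig())
        v_nb = np.sort(included_volumes(nb))
        q = np.arange(1, v_out.size + 1) / (v_out.size + 1)
        np.testing.assert_allclose(v_out, np.quantile(v_nb, q), rtol=1e-4)

    def test_mean_count_rule(self):
        import pandas as pd

        from coultertrace import FilterConfig
        from coultertrace.pipeline import filter_noise_floor

        files = self._neighbors()
        a, b = files[0], files[1]
        counts = []
        for nb in (a, b):
            ev = filter_noise_floor(decode_file_events(nb), FilterConfig())
            counts.append(included_volumes(ev).size)
        interp = interpolate_file(a, b)
        assert interp.n_pulses == round(np.mean(counts))

    def test_uniform_neighbors_quantile_midpoint(self):
        """Neighbors uniform on [10,20] and [14,24] interpolate to ~[12,22]."""
        from coultertrace import InstrumentHeader, MeasurementFile, TimeSection
        from coultertrace.pipeline import diameter_to_height, volume_to_diameter

        header = InstrumentHeader(kd=1.0, gain=1.0, current=1.0)
        rng = np.random.default_rng(5)

        def make(lo, hi, start):
            from dataclasses import replace

            v = rng.uniform(lo, hi, 20_000)
            heights = np.rint(
                diameter_to_height(volume_to_diameter(v), header)
            ).astype(np.int64)
            pulses = np.zeros((v.size, 5), np.int64)
            pulses[:, 0] = heights
            n_ticks = 750
            edges = np.arange(1, n_ticks + 1) * 200
            cum = np.linspace(0, v.size, n_ticks).astype(np.int64)
            cum[-1] = v.size
            h = replace(header, start_time_s=start)
            return MeasurementFile(h, pulses, TimeSection(edges, cum))

        a = make(10, 20, 0.0)
        b = make(14, 24, 200.0)
        from coultertrace import FilterConfig

        interp = interpolate_file(a, b, filter_cfg=FilterConfig(0.0))
        v = included_volumes(decode_file_events(interp))
        assert v.min() == pytest.approx(12.0, abs=0.2)
        assert v.max() == pytest.approx(22.0, abs=0.2)
        # interior quantiles midway between the neighbors'
        assert np.quantile(v, 0.5) == pytest.approx(17.0, abs=0.2)

    def test_flagged_neighbor_rejected(self):
        files = self._neighbors()
        interp = interpolate_file(files[0], files[1])
        with pytest.raises(ConfigError):
            interpolate_file(interp, files[1])

    def test_provenance_interpolated(self):
        files = self._neighbors()
        assert interpolate_file(files[0], files[1]).provenance == "interpolated"


class TestCleanTimecourse:
    def _course(self, debris=(), seed=0, n_files_min=20.0):
        cfg = SimulationConfig(
            populations=[PopulationSpec(1.0, 40.0, 0.15, "none", 0.0)],
            total_duration_min=n_files_min,
            pulses_per_file=8000,
            debris_events=[
                DebrisSpec(d, 0.05) if isinstance(d, int) else DebrisSpec(*d)
                for d in debris
            ],
            seed=seed,
        )
        files, _ = generate_timecourse(cfg)
        return timecourse_from_files(files)

    def test_no_flags_identity(self):
        tc = self._course()
        cleaned, report = clean_timecourse(tc)
        assert not report.flagged.any()
        assert cleaned.files == tc.files

    def test_single_flag_single_replacement(self):
        tc = self._course(debris=[2])
        cleaned, report = clean_timecourse(tc)
        assert report.flagged.sum() == 1
        prov = [f.provenance for f in cleaned]
        assert prov.count("interpolated") == 1
        assert prov[2] == "interpolated"

    def test_consecutive_run_replaced_with_time_weights(self):
        # a run of equally-inflated files hides from the "both" rule (each
        # matches its inflated neighbor); the literal "either" rule sees it
        tc = self._course(debris=[2, 3], n_files_min=30.0)
        cleaned, report = clean_timecourse(
            tc, DebrisConfig(neighbor_rule="either")
        )
        assert report.flagged.tolist()[2:4] == [True, True]
        assert [f.provenance for f in cleaned][2:4] == ["interpolated"] * 2
        # time-proportional weighting: medians sit between the neighbors',
        # the earlier replacement closer to the earlier neighbor
        meds = []
        for i in (1, 2, 3, 4):
            meds.append(
                np.median(included_volumes(decode_file_events(cleaned.files[i])))
            )
        assert meds[0] < meds[1] < meds[2] < meds[3] or np.allclose(
            meds, meds[0], rtol=0.02
        )
        w2 = (cleaned.files[2].header.start_time_s - tc.files[1].header.start_time_s) / (
            tc.files[4].header.start_time_s - tc.files[1].header.start_time_s
        )
        assert 0 < w2 < 0.5  # first of the run leans on the earlier neighbor

    def test_abort_on_majority_flagged(self):
        # escalating inflation: each file exceeds its predecessor by >2.5%
        tc = self._course(
            debris=[(1, 0.05), (2, 0.10), (3, 0.16)], n_files_min=17.0
        )  # 5 files
        with pytest.raises(QCAbortError):
            clean_timecourse(tc, DebrisConfig(neighbor_rule="either"))

    def test_idempotent(self):
        tc = self._course(debris=[2])
        once, _ = clean_timecourse(tc)
        twice, report2 = clean_timecourse(once)
        assert not report2.flagged.any()
        assert twice.files == once.files
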