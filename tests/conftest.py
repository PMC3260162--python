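import numpy as np
import pytest

from coultertrace import (
    InstrumentHeader,
    MeasurementFile,
    TimeSection,
    generate_timecourse,
    preset,
    timecourse_from_files,
)


@pytest.fixture
def unit_header() -> InstrumentHeader:
    """Header with unit calibration constants: d = (h/countsPerVolt)^(1/3)."""
    return InstrumentHeader(kd=1.0, gain=1.0, current=1.0)


@pytest.fixture
def small_file(unit_header) -> MeasurementFile:
    """Three-pulse file with a simple two-tick time section."""
    pulses = np.array(
        [[500, 1, 2, 3, 4], [838870, 0, 0, 0, 0], [1000, 9, 9, 9, 9]],
        dtype=np.int64,
    )
    section = TimeSection([200, 400], [2, 3])
    return MeasurementFile(unit_header, pulses, section)


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale simulated timecourse with ground truth (beads-like)."""
    cfg = preset("beads4um", seed=42, pulses_per_file=800, total_duration_min=20)
    files, truth = generate_timecourse(cfg)
    return files, truth


@pytest.fixture(scope="session")
def small_timecourse(small_sim):
    files, _ = small_sim
    return timecourse_from_files(files)
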