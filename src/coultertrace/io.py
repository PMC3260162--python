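"""Reading, writing, and stitching of instrument pulse files.

A Beckman-Coulter Multisizer-style recording stores, per 150 s file, a
header of calibration constants, one record of five integers per particle
pulse (the first integer carries the pulse height), and a time section that
logs every 200 ms the elapsed time and the cumulative number of pulses seen
so far.  The commercial software resets the clock of every file to zero, so
building a multi-hour timecourse requires re-anchoring each file on a common
epoch — that is what :func:`load_timecourse` does.

The canonical on-disk format here is a documented plain-text *fixture
dialect* that captures every field the native binary layout carries
(see :data:`MAGIC`).  The native ``*.#m4`` byte layout can be plugged in
later behind the same ``dialect`` switch without touching analysis code.
Plain CSV event tables (``time_s, volume_um3``) are supported for
interoperability via :func:`read_event_csv` / :func:`write_event_csv`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, FormatError

MAGIC = "#COULTERTRACE 1"

#: Hard cap on pulses per file imposed by the commercial software.
PULSE_CAP = 525_000

#: Instrument ADC scale: counts per volt.
COUNTS_PER_VOLT = 838_870

_HEADER_FIELDS = {
    "Kd": float,
    "gain": float,
    "current": float,
    "countsPerVolt": float,
    "apertureDiameter": float,
    "startTime": float,
    "duration": float,
    "correctionFactor": int,
}


@dataclass
class InstrumentHeader:
    """Calibration constants reported in the header of each file.

    Parameters
    ----------
    kd :
        Aperture calibration constant (µm per cube-root volt).
    gain, current :
        Dimensionless gain and aperture current (instrument units).
    counts_per_volt :
        ADC scale; 838 870 counts per volt on the Multisizer 4.
    aperture_diameter_um :
        Aperture diameter in µm (100 µm in the reference setup).
    start_time_s :
        Absolute start of this recording, seconds since the timecourse
        epoch (earliest file's start).
    duration_s :
        Recording length in seconds (typically 150).
    correction_factor :
        Integer counts added to the first encoded pulse value to obtain
        the pulse height.
    """

    kd: float
    gain: float
    current: float
    counts_per_volt: float = float(COUNTS_PER_VOLT)
    aperture_diameter_um: float = 100.0
    start_time_s: float = 0.0
    duration_s: float = 150.0
    correction_factor: int = 0

    def __post_init__(self) -> None:
        for name in ("kd", "gain", "current", "counts_per_volt"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"header constant {name!r} must be positive")
        if not self.duration_s > 0:
            raise ConfigError("duration_s must be positive")
        if self.start_time_s < 0:
            raise ConfigError("start_time_s must be >= 0")


@dataclass
class TimeSection:
    """Per-file clock: (elapsed ms, cumulative pulse count) every tick."""

    elapsed_ms: np.ndarray
    cumulative_count: np.ndarray
    tick_width_ms: int = 200

    def __post_init__(self) -> None:
        self.elapsed_ms = np.asarray(self.elapsed_ms, dtype=np.int64)
        self.cumulative_count = np.asarray(self.cumulative_count, dtype=np.int64)
        if self.elapsed_ms.shape != self.cumulative_count.shape:
            raise ConsistencyError("time section arrays must have equal length")
        if self.elapsed_ms.size:
            if np.any(np.diff(self.elapsed_ms) <= 0):
                raise ConsistencyError("elapsed_ms must be strictly increasing")
            if np.any(self.elapsed_ms % self.tick_width_ms != 0):
                raise ConsistencyError(
                    f"elapsed_ms must be multiples of the {self.tick_width_ms} ms tick"
                )
            if np.any(np.diff(self.cumulative_count) < 0):
                raise ConsistencyError("cumulative_count must be non-decreasing")

    @property
    def final_count(self) -> int:
        return int(self.cumulative_count[-1]) if self.cumulative_count.size else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSection):
            return NotImplemented
        return (
            self.tick_width_ms == other.tick_width_ms
            and np.array_equal(self.elapsed_ms, other.elapsed_ms)
            and np.array_equal(self.cumulative_count, other.cumulative_count)
        )


def validate_pulse_record(values: Sequence[int]) -> np.ndarray:
    """Validate a single raw pulse record: exactly five non-negative ints."""
    arr = np.asarray(values, dtype=np.int64)
    if arr.shape != (5,):
        raise FormatError("a pulse record must have exactly five values")
    if np.any(arr < 0):
        raise FormatError("pulse record values must be non-negative")
    return arr


@dataclass
class MeasurementFile:
    """One instrument recording: header, pulse table, time section.

    ``pulses`` is an ``(n, 5)`` integer array — one row per particle, the
    first column being the encoded pulse-height component.  ``provenance``
    is ``"raw"`` for instrument data and ``"interpolated"`` for files
    synthesized by QC to replace debris-corrupted recordings.
    """

    header: InstrumentHeader
    pulses: np.ndarray
    time_section: TimeSection
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.pulses = np.asarray(self.pulses, dtype=np.int64)
        if self.pulses.size == 0:
            self.pulses = self.pulses.reshape(0, 5)
        if self.pulses.ndim != 2 or self.pulses.shape[1] != 5:
            raise FormatError("pulses must be an (n, 5) integer array")
        if np.any(self.pulses < 0):
            raise FormatError("pulse values must be non-negative")
        if self.provenance not in ("raw", "interpolated"):
            raise ConfigError(f"unknown provenance {self.provenance!r}")
        self.validate()

    @property
    def n_pulses(self) -> int:
        return self.pulses.shape[0]

    def validate(self) -> None:
        if self.n_pulses > PULSE_CAP:
            raise ConsistencyError(
                f"{self.n_pulses} pulses exceeds the {PULSE_CAP} per-file cap"
            )
        if self.time_section.final_count != self.n_pulses:
            raise ConsistencyError(
                "time section final cumulative count "
                f"({self.time_section.final_count}) does not match the pulse "
                f"count ({self.n_pulses})"
            )

    @property
    def interval(self) -> tuple[float, float]:
        """Recording interval (start, end) in seconds on the common epoch."""
        return (
            self.header.start_time_s,
            self.header.start_time_s + self.header.duration_s,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementFile):
            return NotImplemented
        return (
            self.header == other.header
            and self.provenance == other.provenance
            and np.array_equal(self.pulses, other.pulses)
            and self.time_section == other.time_section
        )


@dataclass
class Timecourse:
    """An ordered, non-overlapping sequence of measurement files sharing a
    common time epoch (the earliest file's start time)."""

    files: list[MeasurementFile]

    def __post_init__(self) -> None:
        starts = [f.header.start_time_s for f in self.files]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConsistencyError("file start times must be strictly increasing")
        for i, (a, b) in enumerate(zip(self.files, self.files[1:])):
            if b.interval[0] < a.interval[1]:
                raise ConsistencyError(
                    f"recording intervals of files {i} and {i + 1} overlap: "
                    f"{a.interval} vs {b.interval}"
                )

    @property
    def epoch_s(self) -> float:
        return self.files[0].header.start_time_s if self.files else 0.0

    @property
    def global_offsets_s(self) -> np.ndarray:
        """Per-file start time relative to the timecourse epoch."""
        return np.array([f.header.start_time_s - self.epoch_s for f in self.files])

    @property
    def n_pulses(self) -> int:
        return sum(f.n_pulses for f in self.files)

    def __len__(self) -> int:
        return len(self.files)

    def __iter__(self):
        return iter(self.files)


def decode_height(record, header: InstrumentHeader):
    """Pulse height in counts: correction factor plus the first of the five
    per-pulse values, clamped at zero (a pulse cannot have negative
    amplitude).

    ``record`` may be a single five-value record or an ``(n, 5)`` array; the
    return matches (scalar int or int array).
    """
    arr = np.asarray(record, dtype=np.int64)
    if arr.ndim == 1:
        arr = validate_pulse_record(arr)
        return int(max(header.correction_factor + arr[0], 0))
    first = arr[:, 0]
    return np.maximum(header.correction_factor + first, 0)


# ---------------------------------------------------------------------------
# fixture dialect serialization


def _format_header_value(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_measurement_file(mfile: MeasurementFile, path) -> Path:
    """Serialize ``mfile`` to ``path`` in the fixture dialect.

    Round-trips bit-exactly with :func:`read_measurement_file` (floats are
    written with full repr precision).  Refuses files above the 525 000
    pulse cap.
    """
    mfile.validate()
    path = Path(path)
    h = mfile.header
    lines = [MAGIC, "[header]"]
    lines += [
        f"Kd = {_format_header_value(h.kd)}",
        f"gain = {_format_header_value(h.gain)}",
        f"current = {_format_header_value(h.current)}",
        f"countsPerVolt = {_format_header_value(h.counts_per_volt)}",
        f"apertureDiameter = {_format_header_value(h.aperture_diameter_um)}",
        f"startTime = {_format_header_value(h.start_time_s)}",
        f"duration = {_format_header_value(h.duration_s)}",
        f"correctionFactor = {h.correction_factor}",
        f"provenance = {mfile.provenance}",
        f"[pulses] n={mfile.n_pulses}",
    ]
    pulse_lines = [" ".join(map(str, row)) for row in mfile.pulses.tolist()]
    ts = mfile.time_section
    section_lines = [
        f"[timesection] tickWidth={ts.tick_width_ms} n={ts.elapsed_ms.size}"
    ]
    section_lines += [
        f"{int(t)} {int(c)}"
        for t, c in zip(ts.elapsed_ms.tolist(), ts.cumulative_count.tolist())
    ]
    path.write_text("\n".join(lines + pulse_lines + section_lines) + "\n")
    return path


def read_measurement_file(path, dialect: str = "fixture") -> MeasurementFile:
    """Parse one instrument file.

    Only the ``fixture`` dialect is implemented; ``native-adapter`` is the
    hook for a transcription of the vendor ``*.#m4`` byte layout and raises
    ``NotImplementedError`` until one is supplied.
    """
    if dialect == "native-adapter":
        raise NotImplementedError(
            "the native *.#m4 adapter requires the vendor byte layout"
        )
    if dialect != "fixture":
        raise ConfigError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or lines[0].strip() != MAGIC:
        raise FormatError(f"{path}: missing fixture-dialect magic {MAGIC!r}")
    if len(lines) < 2 or lines[1].strip() != "[header]":
        raise FormatError(f"{path}: expected [header] section")

    raw: dict[str, str] = {}
    i = 2
    while i < len(lines) and not lines[i].startswith("[pulses]"):
        line = lines[i].strip()
        if line:
            if "=" not in line:
                raise FormatError(f"{path}: malformed header line {i + 1}: {line!r}")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        i += 1
    if i >= len(lines):
        raise FormatError(f"{path}: missing [pulses] section")

    for name in _HEADER_FIELDS:
        if name not in raw:
            raise FormatError(f"{path}: missing header constant {name!r}")
    provenance = raw.get("provenance", "raw")
    header = InstrumentHeader(
        kd=float(raw["Kd"]),
        gain=float(raw["gain"]),
        current=float(raw["current"]),
        counts_per_volt=float(raw["countsPerVolt"]),
        aperture_diameter_um=float(raw["apertureDiameter"]),
        start_time_s=float(raw["startTime"]),
        duration_s=float(raw["duration"]),
        correction_factor=int(raw["correctionFactor"]),
    )

    n_pulses = _section_count(path, lines[i], "[pulses]")
    first_pulse = i + 1
    pulse_rows = lines[first_pulse : first_pulse + n_pulses]
    if len(pulse_rows) < n_pulses:
        offset = sum(len(l) + 1 for l in lines[: first_pulse + len(pulse_rows)])
        raise FormatError(
            f"{path}: truncated pulse block at byte offset {offset}: expected "
            f"{n_pulses} records, found {len(pulse_rows)}"
        )
    if n_pulses:
        try:
            pulses = np.array(
                [row.split() for row in pulse_rows], dtype=np.int64
            )
        except ValueError as exc:
            raise FormatError(f"{path}: malformed pulse record: {exc}") from exc
        if pulses.shape[1] != 5:
            raise FormatError(
                f"{path}: pulse records must have five values, "
                f"found {pulses.shape[1]}"
            )
    else:
        pulses = np.empty((0, 5), dtype=np.int64)

    j = first_pulse + n_pulses
    if j >= len(lines) or not lines[j].startswith("[timesection]"):
        raise FormatError(f"{path}: missing [timesection] section")
    tick_width = _section_kv(path, lines[j], "tickWidth")
    n_ticks = _section_count(path, lines[j], "[timesection]")
    tick_rows = lines[j + 1 : j + 1 + n_ticks]
    if len(tick_rows) < n_ticks:
        raise FormatError(
            f"{path}: truncated time section: expected {n_ticks} ticks, "
            f"found {len(tick_rows)}"
        )
    if n_ticks:
        ticks = np.array([row.split() for row in tick_rows], dtype=np.int64)
        section = TimeSection(ticks[:, 0], ticks[:, 1], tick_width_ms=tick_width)
    else:
        section = TimeSection(
            np.empty(0, np.int64), np.empty(0, np.int64), tick_width_ms=tick_width
        )

    mfile = MeasurementFile(
        header=header, pulses=pulses, time_section=section, provenance=provenance
    )
    return mfile


def _section_count(path, line: str, tag: str) -> int:
    try:
        return int(line.split("n=")[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed {tag} line: {line!r}") from exc


def _section_kv(path, line: str, key: str) -> int:
    try:
        return int(line.split(f"{key}=")[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: missing {key} in {line!r}") from exc


def load_timecourse(paths: Iterable, dialect: str = "fixture") -> Timecourse:
    """Read several files and stitch them onto a common time axis.

    Files are sorted by header ``startTime``; recording gaps (flush
    intervals between files) are preserved, not compressed.  Files with
    differing calibration constants trigger a warning, overlapping
    recording intervals an error.
    """
    import warnings

    files = [read_measurement_file(p, dialect=dialect) for p in paths]
    if not files:
        raise ConfigError("load_timecourse requires at least one file")
    files.sort(key=lambda f: f.header.start_time_s)
    ref = files[0].header
    for f in files[1:]:
        h = f.header
        if (h.kd, h.gain, h.current, h.counts_per_volt, h.aperture_diameter_um) != (
            ref.kd,
            ref.gain,
            ref.current,
            ref.counts_per_volt,
            ref.aperture_diameter_um,
        ):
            warnings.warn(
                "files in a timecourse have differing calibration constants",
                stacklevel=2,
            )
            break
    return Timecourse(files)


def timecourse_from_files(files: Sequence[MeasurementFile]) -> Timecourse:
    """Build a Timecourse from in-memory files (sorted by start time)."""
    return Timecourse(sorted(files, key=lambda f: f.header.start_time_s))


# ---------------------------------------------------------------------------
# CSV event tables

EVENT_CSV_COLUMNS = [
    "file_index",
    "time_s",
    "height_counts",
    "diameter_um",
    "volume_um3",
    "noise_excluded",
    "bounds_excluded",
]


def write_event_csv(events: pd.DataFrame, path) -> Path:
    """Write a decoded event table as CSV (interoperability format)."""
    path = Path(path)
    cols = [c for c in EVENT_CSV_COLUMNS if c in events.columns]
    events.to_csv(path, index=False, columns=cols)
    return path


def read_event_csv(path) -> pd.DataFrame:
    """Read a plain (time, volume) event table; extra columns are kept."""
    df = pd.read_csv(path)
    for required in ("time_s", "volume_um3"):
        if required not in df.columns:
            raise FormatError(f"{path}: event CSV missing column {required!r}")
    return df
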