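"""Raw pulses -> timestamped volume events, plus the standard filters.

The instrument does not timestamp individual pulses.  Every 200 ms it logs
elapsed time and the cumulative pulse count, so the pulses that arrived
inside one tick are *linearly distributed* across it: the m pulses in tick
(t_{k-1}, t_k] are assigned times t_{k-1} + j*(t_k - t_{k-1})/m, j = 1..m.
Any assigned time is therefore within one tick width (200 ms) of the true
arrival time.

Pulse height h (counts) converts to the spherical-equivalent (Heywood)
diameter through the instrument calibration

    d = Kd * (gain * h / (current * countsPerVolt))^(1/3)   [µm]

and volume is the sphere volume v = π/6 · d³ [µm³].

Two event filters follow the standard cleaning protocol: the lowest 2 % of
each file's events by volume are flagged as instrument noise, and events
outside a configured exclusion bound pair (typically the 10 % bound pair of
the file's histogram) are flagged out of rate analysis.  Filters *flag*
events rather than delete them so that colormaps can still display the full
distribution with the exclusion bounds drawn as overlays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .io import InstrumentHeader, MeasurementFile, TimeSection, Timecourse, decode_height

SPHERE_FACTOR = math.pi / 6.0


@dataclass
class FilterConfig:
    """Event-filter settings.

    noise_floor_fraction : fraction of each file's lowest-volume events
        flagged as instrument noise (default 0.02, i.e. the lowest 2 %).
    exclusion_bound_level : bound-pair level (percent of histogram mode)
        outside which events are flagged out of rate analysis (default 10).
    """

    noise_floor_fraction: float = 0.02
    exclusion_bound_level: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_floor_fraction < 1.0:
            raise ConfigError("noise_floor_fraction must be in [0, 1)")
        if not 0.0 < self.exclusion_bound_level <= 100.0:
            raise ConfigError("exclusion_bound_level must be in (0, 100]")


def assign_pulse_times(section: TimeSection, file_start_s: float = 0.0) -> np.ndarray:
    """Per-pulse timestamps (seconds) from a file's time section.

    The m pulses recorded in tick interval (t_{k-1}, t_k] receive times
    t_{k-1} + j*(t_k - t_{k-1})/m for j = 1..m (a single pulse lands at the
    tick's end), shifted by ``file_start_s``.
    """
    cum = np.asarray(section.cumulative_count, dtype=np.int64)
    t_ms = np.asarray(section.elapsed_ms, dtype=np.float64)
    if cum.size == 0:
        return np.empty(0, dtype=np.float64)
    if np.any(np.diff(cum) < 0):
        raise ConsistencyError("cumulative pulse count decreases within the file")
    counts = np.diff(np.concatenate(([0], cum)))
    starts = np.concatenate(([0.0], t_ms[:-1]))
    widths = t_ms - starts
    n = int(cum[-1])
    if n == 0:
        return np.empty(0, dtype=np.float64)
    # j-th pulse (1-based) within its tick
    tick_of_pulse = np.repeat(np.arange(cum.size), counts)
    first_in_tick = np.repeat(np.concatenate(([0], cum[:-1])), counts)
    j = np.arange(n) - first_in_tick + 1
    m = counts[tick_of_pulse].astype(np.float64)
    times_ms = starts[tick_of_pulse] + j * widths[tick_of_pulse] / m
    return file_start_s + times_ms / 1000.0


def height_to_diameter(height, header: InstrumentHeader):
    """Heywood (spherical-equivalent) diameter in µm from pulse height.

    Strictly increasing in height with d(0) = 0; every calibration constant
    comes from the file header.
    """
    for name in ("kd", "gain", "current", "counts_per_volt"):
        if not getattr(header, name) > 0:
            raise ConfigError(f"header constant {name!r} must be positive")
    h = np.asarray(height, dtype=np.float64)
    d = header.kd * np.cbrt(
        header.gain * h / (header.current * header.counts_per_volt)
    )
    return float(d) if np.isscalar(height) else d


def diameter_to_volume(diameter_um):
    """Sphere volume π/6·d³ in µm³."""
    d = np.asarray(diameter_um, dtype=np.float64)
    v = SPHERE_FACTOR * d**3
    return float(v) if np.isscalar(diameter_um) else v


def volume_to_diameter(volume_um3):
    """Inverse of :func:`diameter_to_volume`."""
    v = np.asarray(volume_um3, dtype=np.float64)
    d = np.cbrt(v / SPHERE_FACTOR)
    return float(d) if np.isscalar(volume_um3) else d


def diameter_to_height(diameter_um, header: InstrumentHeader):
    """Exact (unrounded) pulse height corresponding to a diameter.

    Inverse of :func:`height_to_diameter`; used by the simulator to encode
    generated volumes back into instrument counts.
    """
    d = np.asarray(diameter_um, dtype=np.float64)
    h = (d / header.kd) ** 3 * header.current * header.counts_per_volt / header.gain
    return float(h) if np.isscalar(diameter_um) else h


def decode_file_events(
    mfile: MeasurementFile, file_index: int = 0, epoch_s: float = 0.0
) -> pd.DataFrame:
    """Decode one file into an event table.

    Columns: file_index, time_s (on the timecourse epoch), height_counts,
    diameter_um, volume_um3, noise_excluded, bounds_excluded (filters
    initialised to False).
    """
    heights = decode_height(mfile.pulses, mfile.header)
    times = assign_pulse_times(
        mfile.time_section, mfile.header.start_time_s - epoch_s
    )
    if times.size != mfile.n_pulses:
        raise ConsistencyError(
            f"time section yields {times.size} timestamps for "
            f"{mfile.n_pulses} pulses"
        )
    diam = height_to_diameter(heights, mfile.header)
    return pd.DataFrame(
        {
            "file_index": np.full(mfile.n_pulses, file_index, dtype=np.int64),
            "time_s": times,
            "height_counts": heights,
            "diameter_um": diam,
            "volume_um3": diameter_to_volume(diam),
            "noise_excluded": np.zeros(mfile.n_pulses, dtype=bool),
            "bounds_excluded": np.zeros(mfile.n_pulses, dtype=bool),
        }
    )


def decode_timecourse_events(timecourse: Timecourse) -> pd.DataFrame:
    """Decode every file of a timecourse onto the common epoch."""
    epoch = timecourse.epoch_s
    frames = [
        decode_file_events(f, file_index=i, epoch_s=epoch)
        for i, f in enumerate(timecourse)
    ]
    return pd.concat(frames, ignore_index=True)


def filter_noise_floor(events: pd.DataFrame, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Flag the lowest ``noise_floor_fraction`` of one file's events by
    volume as instrument noise.

    Exactly floor(fraction·N) events are flagged — those of smallest
    volume, ties broken by original record order (stable).  Event order is
    preserved; the operation is idempotent.
    """
    cfg = cfg or FilterConfig()
    events = events.copy()
    n = len(events)
    k = int(math.floor(cfg.noise_floor_fraction * n))
    flags = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(events["volume_um3"].to_numpy(), kind="stable")
        flags[order[:k]] = True
    events["noise_excluded"] = flags
    return events


def apply_exclusion_bounds(events: pd.DataFrame, bounds) -> pd.DataFrame:
    """Flag events whose volume falls outside [bounds.lower, bounds.upper].

    The interval is closed: events exactly on a bound are retained.  Order
    preserved; idempotent.
    """
    if bounds.lower > bounds.upper:
        raise ConfigError("exclusion bounds must satisfy lower <= upper")
    events = events.copy()
    v = events["volume_um3"].to_numpy()
    events["bounds_excluded"] = (v < bounds.lower) | (v > bounds.upper)
    return events


def included_volumes(events: pd.DataFrame) -> np.ndarray:
    """Volumes of events passing every filter flag present in the table."""
    mask = np.ones(len(events), dtype=bool)
    for col in ("noise_excluded", "bounds_excluded"):
        if col in events.columns:
            mask &= ~events[col].to_numpy()
    return events["volume_um3"].to_numpy()[mask]


def included_events(events: pd.DataFrame) -> pd.DataFrame:
    """Subset of events passing every filter flag."""
    mask = np.ones(len(events), dtype=bool)
    for col in ("noise_excluded", "bounds_excluded"):
        if col in events.columns:
            mask &= ~events[col].to_numpy()
    return events.loc[mask]
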