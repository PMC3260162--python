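"""Debris-file detection and replacement by interpolation.

Debris occasionally partially occludes the instrument aperture, which
abruptly inflates the apparent size distribution for one or a few 150 s
files until a flush clears it.  Such files are identified by comparing a
specific histogram feature — the 25 % bound pair — against the two
neighboring files: a file whose bound exceeds 1.025 times the corresponding
bound of its neighbors is a "debris" file.  Flagged files are replaced by
data interpolated from the nearest clean neighbors (midpoint quantile
interpolation between the neighbors' empirical volume distributions, with
timestamps linearly spaced across the replaced file's full duration) and
written as new files marked ``provenance = interpolated``.

The comparison at the threshold is inclusive within a tiny relative
tolerance so that a file sitting exactly at the published 1.025 criterion
is flagged deterministically rather than at the mercy of floating-point
rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import features, pipeline
from .errors import ConfigError, ConsistencyError, QCAbortError
from .io import InstrumentHeader, MeasurementFile, TimeSection, Timecourse


@dataclass
class DebrisConfig:
    """Debris-detection settings.

    bound_level : bound-pair level compared across neighbors (percent of
        mode; default 25).
    ratio_threshold : a file is debris when its bound is at least this
        multiple of the neighbors' (default 1.025).
    neighbor_rule : ``"both"`` (default) flags a file only when it exceeds
        the threshold against *both* neighbors, which targets transient
        single-file spikes and tolerates steady monotone growth;
        ``"either"`` is the literal one-neighbor reading.
    compare_side : which member of the bound pair is compared —
        ``"upper"`` (default; occlusions inflate the large-volume tail),
        ``"lower"``, or ``"either"``.
    """

    bound_level: float = 25.0
    ratio_threshold: float = 1.025
    neighbor_rule: str = "both"
    compare_side: str = "upper"
    rel_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 1.0:
            raise ConfigError("ratio_threshold must exceed 1")
        if self.neighbor_rule not in ("both", "either"):
            raise ConfigError("neighbor_rule must be 'both' or 'either'")
        if self.compare_side not in ("upper", "lower", "either"):
            raise ConfigError("compare_side must be 'upper', 'lower' or 'either'")


def file_bounds(
    per_file_volumes: list[np.ndarray], cfg: DebrisConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-file (lower, upper) bound at ``cfg.bound_level`` from each
    file's included volumes."""
    lowers, uppers = [], []
    for v in per_file_volumes:
        hist = features.build_histogram(np.asarray(v))
        bp = features.bound_pair(hist, cfg.bound_level)
        lowers.append(bp.lower)
        uppers.append(bp.upper)
    return np.asarray(lowers), np.asarray(uppers)


def _exceeds(value: np.ndarray, neighbor: np.ndarray, cfg: DebrisConfig) -> np.ndarray:
    ratio = value / neighbor
    return ratio >= cfg.ratio_threshold * (1.0 - cfg.rel_tol)


def debris_flags_from_bounds(bounds: np.ndarray, cfg: DebrisConfig | None = None) -> np.ndarray:
    """Flag files from a per-file bound series.

    File i is flagged iff its bound exceeds ``ratio_threshold`` times the
    bound of its neighbors (both neighbors under the default rule).  The
    first and last files, having only one neighbor, are never flagged.
    """
    cfg = cfg or DebrisConfig()
    b = np.asarray(bounds, dtype=np.float64)
    if b.size < 3:
        raise ConsistencyError("debris detection requires at least 3 files")
    flags = np.zeros(b.size, dtype=bool)
    mid = b[1:-1]
    vs_prev = _exceeds(mid, b[:-2], cfg)
    vs_next = _exceeds(mid, b[2:], cfg)
    if cfg.neighbor_rule == "both":
        flags[1:-1] = vs_prev & vs_next
    else:
        flags[1:-1] = vs_prev | vs_next
    return flags


def detect_debris_files(
    per_file_volumes: list[np.ndarray] | Timecourse,
    cfg: DebrisConfig | None = None,
    filter_cfg: pipeline.FilterConfig | None = None,
) -> pd.DataFrame:
    """Detect debris files in a timecourse.

    Accepts either a :class:`Timecourse` (files are decoded and
    noise-filtered first) or a list of per-file included-volume arrays.
    Returns a QC report with columns file_index, bound_value, ratio_prev,
    ratio_next, flagged.
    """
    cfg = cfg or DebrisConfig()
    volumes = _per_file_volumes(per_file_volumes, filter_cfg)
    if len(volumes) < 3:
        raise ConsistencyError("debris detection requires at least 3 files")
    lowers, uppers = file_bounds(volumes, cfg)
    sides = {"upper": [uppers], "lower": [lowers], "either": [uppers, lowers]}[
        cfg.compare_side
    ]
    flags = np.zeros(len(volumes), dtype=bool)
    for series in sides:
        flags |= debris_flags_from_bounds(series, cfg)
    primary = sides[0]
    ratio_prev = np.full(len(volumes), np.nan)
    ratio_next = np.full(len(volumes), np.nan)
    ratio_prev[1:] = primary[1:] / primary[:-1]
    ratio_next[:-1] = primary[:-1] / primary[1:]
    return pd.DataFrame(
        {
            "file_index": np.arange(len(volumes)),
            "bound_value": primary,
            "ratio_prev": ratio_prev,
            "ratio_next": ratio_next,
            "flagged": flags,
        }
    )


def _per_file_volumes(
    source, filter_cfg: pipeline.FilterConfig | None
) -> list[np.ndarray]:
    if isinstance(source, Timecourse):
        fcfg = filter_cfg or pipeline.FilterConfig()
        out = []
        for i, mf in enumerate(source):
            ev = pipeline.decode_file_events(mf, file_index=i, epoch_s=source.epoch_s)
            ev = pipeline.filter_noise_floor(ev, fcfg)
            out.append(pipeline.included_volumes(ev))
        return out
    return [np.asarray(v, dtype=np.float64) for v in source]


def interpolate_file(
    prev: MeasurementFile,
    nxt: MeasurementFile,
    like: MeasurementFile | None = None,
    weight: float = 0.5,
    filter_cfg: pipeline.FilterConfig | None = None,
) -> MeasurementFile:
    """Synthesize a replacement file from two clean neighbors.

    The replacement carries round(weighted mean of the neighbors' included
    counts) pulses; its volume distribution is the quantile-wise weighted
    midpoint of the neighbors' empirical distributions (volume_j mixes the
    neighbors' j/(m+1) quantiles), and its timestamps are linearly spaced
    across the replaced file's full duration.  ``weight`` is the weight of
    the *next* neighbor (0.5 for an isolated flagged file; time-proportional
    for runs).  Pulse records are synthesized with only the height field
    meaningful; provenance is ``"interpolated"``.
    """
    for nb, name in ((prev, "prev"), (nxt, "next")):
        if nb.provenance != "raw":
            raise ConfigError(f"{name} neighbor is not a raw file")
    if not 0.0 <= weight <= 1.0:
        raise ConfigError("weight must be in [0, 1]")
    fcfg = filter_cfg or pipeline.FilterConfig()
    vols = []
    counts = []
    for nb in (prev, nxt):
        ev = pipeline.filter_noise_floor(pipeline.decode_file_events(nb), fcfg)
        v = pipeline.included_volumes(ev)
        vols.append(np.sort(v))
        counts.append(v.size)
    m = int(round((1.0 - weight) * counts[0] + weight * counts[1]))
    template = like if like is not None else prev
    header = InstrumentHeader(
        kd=template.header.kd,
        gain=template.header.gain,
        current=template.header.current,
        counts_per_volt=template.header.counts_per_volt,
        aperture_diameter_um=template.header.aperture_diameter_um,
        start_time_s=template.header.start_time_s,
        duration_s=template.header.duration_s,
        correction_factor=template.header.correction_factor,
    )
    q = np.arange(1, m + 1) / (m + 1)
    v_interp = (1.0 - weight) * np.quantile(vols[0], q) + weight * np.quantile(
        vols[1], q
    )
    # shuffle-free deterministic layout: volumes linearly spaced in time by
    # quantile order would correlate size with time; interleave instead via
    # a fixed stride permutation so each 200 ms tick sees the full range.
    perm = _stride_permutation(m)
    v_series = v_interp[perm]
    heights = np.rint(
        pipeline.diameter_to_height(
            pipeline.volume_to_diameter(v_series), header
        )
    ).astype(np.int64)
    first = np.maximum(heights - header.correction_factor, 0)
    pulses = np.zeros((m, 5), dtype=np.int64)
    pulses[:, 0] = first
    times_ms = (np.arange(1, m + 1) - 0.5) / m * header.duration_s * 1000.0
    section = _time_section_from_times(times_ms, header.duration_s)
    return MeasurementFile(
        header=header, pulses=pulses, time_section=section, provenance="interpolated"
    )


def _stride_permutation(m: int) -> np.ndarray:
    if m <= 1:
        return np.arange(m)
    stride = max(int(np.sqrt(m)), 1)
    while np.gcd(stride, m) != 1:
        stride += 1
    return (np.arange(m) * stride) % m


def _time_section_from_times(times_ms: np.ndarray, duration_s: float, tick_ms: int = 200) -> TimeSection:
    n_ticks = int(np.ceil(duration_s * 1000.0 / tick_ms))
    edges = (np.arange(1, n_ticks + 1)) * tick_ms
    cum = np.searchsorted(np.sort(times_ms), edges, side="right")
    cum[-1] = times_ms.size
    return TimeSection(edges, cum, tick_width_ms=tick_ms)


def clean_timecourse(
    timecourse: Timecourse,
    cfg: DebrisConfig | None = None,
    filter_cfg: pipeline.FilterConfig | None = None,
    max_flagged_fraction: float = 0.5,
) -> tuple[Timecourse, pd.DataFrame]:
    """Detect debris files and replace them with interpolated data.

    Single pass: detect, then replace each flagged file from its nearest
    unflagged neighbors.  Runs of consecutive flagged files are all
    replaced from the bracketing unflagged files with time-proportional
    quantile weights.  Aborts (QCAbortError) when more than
    ``max_flagged_fraction`` of files are flagged — that pattern suggests a
    persistent occlusion the interpolation rule cannot fix.

    Returns the cleaned timecourse and the QC report (detection report plus
    a ``replaced`` column).  Input files are not modified.
    """
    cfg = cfg or DebrisConfig()
    report = detect_debris_files(timecourse, cfg, filter_cfg)
    flags = report["flagged"].to_numpy()
    report = report.copy()
    report["replaced"] = flags.copy()
    n_flagged = int(flags.sum())
    if n_flagged > max_flagged_fraction * len(flags):
        raise QCAbortError(
            f"{n_flagged}/{len(flags)} files flagged as debris — likely a "
            "persistent aperture occlusion; refusing to interpolate"
        )
    if n_flagged == 0:
        return timecourse, report

    files = list(timecourse.files)
    new_files = list(files)
    i = 0
    while i < len(files):
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(files) and flags[j + 1]:
            j += 1
        prev_i, next_i = i - 1, j + 1  # edges are never flagged
        t_prev = files[prev_i].header.start_time_s
        t_next = files[next_i].header.start_time_s
        for k in range(i, j + 1):
            w = (files[k].header.start_time_s - t_prev) / (t_next - t_prev)
            new_files[k] = interpolate_file(
                files[prev_i],
                files[next_i],
                like=files[k],
                weight=w,
                filter_cfg=filter_cfg,
            )
        i = j + 1
    return Timecourse(new_files), report
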