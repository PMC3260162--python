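"""Per-file volume-distribution features.

A 150 s file's volume histogram is summarised by its *mode* (the smoothed
count maximum) and by *bound pairs*: for a level X, the pair of volumes —
one on each side of the mode — at which the smoothed count crosses X % of
the mode count.  Bound pairs condense histogram shape into a handful of
trajectories that can be tracked across hundreds of files: the 10 % pair
typically serves as the exclusion bounds for rate analysis, the 25 % pair
feeds the debris-file detector, and following a bound through time tracks
the growth of the small- or large-cell side of the population separately.

When subpopulations emerge (e.g. slow-growing, G1-arrested and
metaphase-arrested cells in a Cdc28-inactivated yeast culture) the smoothed
histogram becomes multi-modal; each local peak is then identified and
tracked individually across files, and events are assigned to the
subpopulation whose histogram region encloses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigError


@dataclass
class VolumeHistogram:
    """Binned volume distribution of one file's included events."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed_counts: np.ndarray
    data_min: float
    data_max: float

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode_index(self) -> int:
        # ties -> lowest volume
        return int(np.argmax(self.smoothed_counts))

    @property
    def mode_volume(self) -> float:
        return float(self.midpoints[self.mode_index])

    @property
    def mode_count(self) -> float:
        return float(self.smoothed_counts[self.mode_index])


@dataclass
class BoundPair:
    """Volumes where the (smoothed) count crosses ``level`` % of the mode
    count, one on each side of the mode.  ``lower_clamped``/``upper_clamped``
    record that no crossing existed on that side and the data extremum was
    returned instead."""

    level: float
    lower: float
    upper: float
    lower_clamped: bool = False
    upper_clamped: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class SubpopulationTrack:
    """One histogram peak followed across consecutive files."""

    label: str
    file_indices: list = field(default_factory=list)
    mode_volumes: list = field(default_factory=list)
    fractions: list = field(default_factory=list)

    def last_mode(self) -> float:
        return self.mode_volumes[-1]


@dataclass
class ColormapMatrix:
    """2-D (volume x time) matrix of relative particle fractions: each
    nonempty time column is normalised to sum to 1."""

    time_bin_edges: np.ndarray
    volume_bin_edges: np.ndarray
    values: np.ndarray  # shape (n_volume_bins, n_time_bins)


def build_histogram(
    volumes: np.ndarray,
    bins: int | np.ndarray = 256,
    binning: str = "log",
    vrange: tuple[float, float] | None = None,
    smoothing_bins: float = 3.0,
) -> VolumeHistogram:
    """Histogram the included volumes of one file.

    Parameters
    ----------
    volumes :
        Included event volumes (µm³); must be nonempty.
    bins :
        Either explicit monotone bin edges or a bin count (default 256).
    binning :
        ``"log"`` (default; suits multiplicative size noise) or
        ``"linear"``; ignored when explicit edges are given.
    vrange :
        (min, max) volume range; defaults to the data range.
    smoothing_bins :
        Gaussian smoothing bandwidth in bins (default 3); 0 disables
        smoothing (smoothed counts equal raw counts).
    """
    v = np.asarray(volumes, dtype=np.float64)
    if v.size == 0:
        raise ConfigError("cannot build a histogram from zero included events")
    if np.isscalar(bins) or np.ndim(bins) == 0:
        lo, hi = vrange if vrange is not None else (float(v.min()), float(v.max()))
        if hi <= lo:  # degenerate: all volumes equal
            if hi > 0:
                lo, hi = lo * 0.999, hi * 1.001
            else:
                lo, hi = lo - 0.5, hi + 0.5
        if binning == "log":
            if lo <= 0:
                raise ConfigError("log binning requires positive volumes")
            edges = np.logspace(np.log10(lo), np.log10(hi), int(bins) + 1)
        elif binning == "linear":
            edges = np.linspace(lo, hi, int(bins) + 1)
        else:
            raise ConfigError(f"unknown binning {binning!r}")
    else:
        edges = np.asarray(bins, dtype=np.float64)
        if np.any(np.diff(edges) <= 0):
            raise ConfigError("bin edges must be strictly increasing")
    counts, edges = np.histogram(v, bins=edges)
    if smoothing_bins > 0:
        smoothed = ndimage.gaussian_filter1d(
            counts.astype(np.float64), sigma=smoothing_bins, mode="nearest"
        )
    else:
        smoothed = counts.astype(np.float64)
    return VolumeHistogram(
        bin_edges=edges,
        counts=counts,
        smoothed_counts=smoothed,
        data_min=float(v.min()),
        data_max=float(v.max()),
    )


def _crossing(
    x: np.ndarray, y: np.ndarray, i_mode: int, target: float, side: int
) -> tuple[float, bool]:
    """Crossing of y through ``target`` nearest the mode on one side.

    ``side`` is -1 (low-volume side) or +1 (high side).  Walk outward from
    the mode; an exact hit returns that midpoint, otherwise linearly
    interpolate between the first bin below target and its inner neighbor.
    Returns (volume, clamped)."""
    i = i_mode
    while True:
        i += side
        if i < 0 or i >= y.size:
            # no crossing on this side: clamp to data extremum
            return (x[0] if side < 0 else x[-1]), True
        if y[i] == target:
            return float(x[i]), False
        if y[i] < target:
            inner = i - side
            frac = (y[inner] - target) / (y[inner] - y[i])
            return float(x[inner] + frac * (x[i] - x[inner])), False


def bound_pair(
    hist: VolumeHistogram, level: float, use_smoothed: bool = True
) -> BoundPair:
    """Bound pair at ``level`` percent of the mode count.

    The target count is level/100 · modeCount; each bound is the crossing
    of the (smoothed, by default) counts through the target nearest the
    mode on that side, linearly interpolated between bin midpoints.  If a
    side never drops below the target, the data extremum is returned with
    the corresponding ``*_clamped`` flag set.  level 100 returns the mode
    itself on both sides.
    """
    if not 0.0 < level <= 100.0:
        raise ConfigError("bound-pair level must be in (0, 100]")
    y = hist.smoothed_counts if use_smoothed else hist.counts.astype(float)
    if y.size == 0:
        raise ConfigError("empty histogram")
    i_mode = int(np.argmax(y))
    target = level / 100.0 * float(y[i_mode])
    x = hist.midpoints
    if target == y[i_mode]:
        mode_v = float(x[i_mode])
        return BoundPair(level=level, lower=mode_v, upper=mode_v)
    lower, lo_clamped = _crossing(x, y, i_mode, target, side=-1)
    upper, hi_clamped = _crossing(x, y, i_mode, target, side=+1)
    if lo_clamped:
        lower = hist.data_min
    if hi_clamped:
        upper = hist.data_max
    return BoundPair(
        level=level,
        lower=lower,
        upper=upper,
        lower_clamped=lo_clamped,
        upper_clamped=hi_clamped,
    )


def find_subpopulation_modes(
    hist: VolumeHistogram,
    min_prominence: float = 0.05,
    min_separation_bins: int = 10,
) -> np.ndarray:
    """Volumes of local peaks of the smoothed histogram.

    Peaks must have prominence at least ``min_prominence`` times the global
    smoothed maximum and be at least ``min_separation_bins`` bins apart;
    closer peaks merge into the stronger one.  A unimodal histogram yields
    exactly one peak, the global mode.  Peaks are returned sorted by volume.
    """
    y = hist.smoothed_counts
    peaks, _ = signal.find_peaks(
        y,
        prominence=min_prominence * float(y.max()),
        distance=max(int(min_separation_bins), 1),
    )
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(y))])
    return np.sort(hist.midpoints[peaks])


def subpopulation_boundaries(hist: VolumeHistogram, peaks: np.ndarray) -> np.ndarray:
    """Volume boundaries between adjacent peaks: the smoothed-count minimum
    between each consecutive peak pair (ties -> lowest volume)."""
    x = hist.midpoints
    y = hist.smoothed_counts
    idx = np.searchsorted(x, peaks)
    idx = np.clip(idx, 0, x.size - 1)
    bounds = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = y[a : b + 1]
        bounds.append(float(x[a + int(np.argmin(seg))]))
    return np.asarray(bounds)


def assign_subpopulations(
    volumes: np.ndarray, hist: VolumeHistogram, peaks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each included event to the subpopulation region enclosing it.

    Regions are delimited by the smoothed-count minima between adjacent
    peaks; an event exactly on a boundary goes to the lower-volume track.
    Returns (labels, fractions): integer track labels per event (0 is the
    smallest-volume track) and the per-track fractions, which sum to 1.
    """
    if len(peaks) == 0:
        raise ConfigError("assign_subpopulations requires at least one peak")
    v = np.asarray(volumes, dtype=np.float64)
    boundaries = subpopulation_boundaries(hist, np.asarray(peaks))
    # 'left' places a boundary-valued event in the lower-volume region
    labels = np.searchsorted(boundaries, v, side="left")
    fractions = np.bincount(labels, minlength=len(peaks)).astype(float)
    fractions /= max(v.size, 1)
    return labels, fractions


def track_modes(
    per_file_peaks: list[np.ndarray],
    max_relative_jump: float = 0.15,
    file_indices: list[int] | None = None,
    per_file_fractions: list[np.ndarray] | None = None,
) -> list[SubpopulationTrack]:
    """Associate histogram peaks across consecutive files into tracks.

    Greedy nearest-neighbor matching between each file's peaks and the
    active tracks' last known modes, subject to a maximum relative jump per
    file (default 15 %).  Unmatched peaks start new tracks; a track missing
    from a file simply records a gap and remains matchable later.
    """
    if file_indices is None:
        file_indices = list(range(len(per_file_peaks)))
    tracks: list[SubpopulationTrack] = []
    for pos, (fi, peaks) in enumerate(zip(file_indices, per_file_peaks)):
        peaks = np.atleast_1d(np.asarray(peaks, dtype=np.float64))
        fracs = None
        if per_file_fractions is not None:
            fracs = np.atleast_1d(per_file_fractions[pos])
        # candidate (relative jump, track, peak) pairs within tolerance
        cands = []
        for ti, tr in enumerate(tracks):
            last = tr.last_mode()
            for pi, p in enumerate(peaks):
                jump = abs(p - last) / last
                if jump <= max_relative_jump:
                    cands.append((jump, ti, pi))
        cands.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        for jump, ti, pi in cands:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tracks[ti].file_indices.append(fi)
            tracks[ti].mode_volumes.append(float(peaks[pi]))
            tracks[ti].fractions.append(
                float(fracs[pi]) if fracs is not None else np.nan
            )
        for pi, p in enumerate(peaks):
            if pi not in used_p:
                tr = SubpopulationTrack(label=f"track{len(tracks)}")
                tr.file_indices.append(fi)
                tr.mode_volumes.append(float(p))
                tr.fractions.append(float(fracs[pi]) if fracs is not None else np.nan)
                tracks.append(tr)
    return tracks


def colormap_matrix(
    times_s: np.ndarray,
    volumes: np.ndarray,
    time_bin_edges: np.ndarray,
    volume_bin_edges: np.ndarray,
) -> ColormapMatrix:
    """Relative particle fraction per (volume, time) cell.

    Counts are normalised within each time column so that every nonempty
    column sums to 1 (the per-measurement relative fraction of particles at
    each volume); empty columns stay all-zero.
    """
    t_edges = np.asarray(time_bin_edges, dtype=np.float64)
    v_edges = np.asarray(volume_bin_edges, dtype=np.float64)
    if np.any(np.diff(t_edges) <= 0) or np.any(np.diff(v_edges) <= 0):
        raise ConfigError("bin edges must be strictly increasing")
    counts, _, _ = np.histogram2d(
        np.asarray(volumes, float), np.asarray(times_s, float), bins=(v_edges, t_edges)
    )
    col_sums = counts.sum(axis=0)
    values = np.divide(
        counts,
        col_sums,
        out=np.zeros_like(counts),
        where=col_sums > 0,
    )
    return ColormapMatrix(
        time_bin_edges=t_edges, volume_bin_edges=v_edges, values=values
    )
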