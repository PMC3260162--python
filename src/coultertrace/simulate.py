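"""Seeded generator of instrument-style volume timecourses with ground truth.

The simulator emulates what the modified Coulter counter records from a
live culture: back-to-back 150 s files separated by flush gaps (~75 % duty
cycle), Poisson pulse counts per file, per-pulse arrival times uniform
within the recording window, and particle volumes drawn from one or more
populations with a log-normal biological size spread around a
time-dependent mean (constant, linear, or exponential growth law).
Multiplicative Gaussian instrument noise acts on the measured diameter.
Optional artifacts reproduce the failure modes the analysis must handle: a
low-volume noise floor of junk events, debris files in which a partial
aperture occlusion inflates every measured volume of one file, and a
treatment response in which the population mean switches to a new linear
slope after a configurable lag.

Generated volumes are encoded back into integer pulse heights by inverting
the instrument calibration, and time sections are built at the 200 ms tick,
so simulator output exercises the full decoding path.  A ``GroundTruth``
record keeps every pulse's true time, volume, and population, plus all
change points.  A fixed seed makes output bit-identical; all draws come
from one generator stream in documented order (per file: count, arrival
times, population labels, biological spread, junk replacement, instrument
noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pipeline
from .errors import ConfigError
from .io import InstrumentHeader, MeasurementFile, TimeSection

#: 4.000 µm beads (NIST-traceable sizing standard): volume π/6·4³.
BEAD_DIAMETER_UM = 4.000
BEAD_DIAMETER_SD_UM = 0.033


@dataclass
class PopulationSpec:
    """One particle population.

    weight : fraction of events drawn from this population.
    mean_volume_um3 : mean volume at t = 0.
    cv : log-normal biological size spread (coefficient of variation).
    growth_law : "none", "linear" (rate in µm³/min) or "exponential"
        (rate in 1/min), applied to the population mean volume.
    """

    weight: float
    mean_volume_um3: float
    cv: float
    growth_law: str = "none"
    rate: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigError("cv must be >= 0")
        if self.growth_law not in ("none", "linear", "exponential"):
            raise ConfigError(f"unknown growth law {self.growth_law!r}")

    def mean_at(self, t_s: np.ndarray) -> np.ndarray:
        """Population mean volume at time t (seconds)."""
        t_min = np.asarray(t_s, dtype=np.float64) / 60.0
        if self.growth_law == "none":
            return np.full_like(t_min, self.mean_volume_um3)
        if self.growth_law == "linear":
            return self.mean_volume_um3 + self.rate * t_min
        return self.mean_volume_um3 * np.exp(self.rate * t_min)


@dataclass
class TreatmentSpec:
    """A treatment at ``time_s`` whose effect begins after ``lag_s``: from
    the change point onward the mean volume follows a linear slope
    ``post_slope_um3_per_min`` continuing from its value at the change
    point."""

    time_s: float
    lag_s: float
    post_slope_um3_per_min: float

    @property
    def change_point_s(self) -> float:
        return self.time_s + self.lag_s


@dataclass
class DebrisSpec:
    """A partial-occlusion artifact: every measured volume of file
    ``file_index`` is inflated by (1 + ``inflation``)."""

    file_index: int
    inflation: float


def default_header() -> InstrumentHeader:
    return InstrumentHeader(kd=1.0, gain=1.0, current=1.0)


@dataclass
class SimulationConfig:
    """Full description of a simulated timecourse; see module docstring."""

    populations: list[PopulationSpec]
    total_duration_min: float = 120.0
    pulses_per_file: float = 20_000.0
    file_duration_s: float = 150.0
    gap_duration_s: float = 50.0  # 150/(150+50) = 75 % duty cycle
    measurement_cv: float = 0.01
    noise_floor_weight: float = 0.0
    debris_events: list[DebrisSpec] = field(default_factory=list)
    treatment: TreatmentSpec | None = None
    header: InstrumentHeader = field(default_factory=default_header)
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(p.weight for p in self.populations)
        if self.populations and abs(w - 1.0) > 1e-9:
            raise ConfigError("population weights must sum to 1")
        for frac in (self.measurement_cv, self.noise_floor_weight):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must be in [0, 1]")
        if self.file_duration_s <= 0 or self.gap_duration_s < 0:
            raise ConfigError("inconsistent durations")
        if self.total_duration_min * 60.0 < self.file_duration_s:
            raise ConfigError("total duration shorter than a single file")

    @property
    def n_files(self) -> int:
        cycle = self.file_duration_s + self.gap_duration_s
        return int(
            (self.total_duration_min * 60.0 + self.gap_duration_s) // cycle
        )


@dataclass
class GroundTruth:
    """Per-pulse truth and all change points of a simulated timecourse."""

    events: pd.DataFrame  # pulse_id, file_index, true_time_s, true_volume_um3,
    #                       measured_volume_um3, population, is_junk
    change_points: list[tuple[float, str]]
    config: SimulationConfig

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)


def _lognormal_multiplier(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-1 log-normal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def generate_timecourse(
    cfg: SimulationConfig,
) -> tuple[list[MeasurementFile], GroundTruth]:
    """Simulate a timecourse; returns measurement files plus ground truth."""
    if not cfg.populations:
        raise ConfigError("at least one population is required")
    rng = np.random.default_rng(cfg.seed)
    header = cfg.header
    tick = 200  # ms
    weights = np.array([p.weight for p in cfg.populations])
    pop_labels = [p.label or f"pop{i}" for i, p in enumerate(cfg.populations)]
    min_mean0 = min(p.mean_volume_um3 for p in cfg.populations)
    debris_by_file = {d.file_index: d.inflation for d in cfg.debris_events}

    files: list[MeasurementFile] = []
    truth_frames: list[pd.DataFrame] = []
    cycle = cfg.file_duration_s + cfg.gap_duration_s
    pulse_id0 = 0
    for fi in range(cfg.n_files):
        start = fi * cycle
        n = int(rng.poisson(cfg.pulses_per_file))
        t_local = np.sort(rng.uniform(0.0, cfg.file_duration_s, size=n))
        t_abs = start + t_local
        pop_idx = rng.choice(len(cfg.populations), size=n, p=weights)
        means = np.empty(n)
        for pi, pop in enumerate(cfg.populations):
            mask = pop_idx == pi
            means[mask] = pop.mean_at(t_abs[mask])
        if cfg.treatment is not None:
            cp = cfg.treatment.change_point_s
            after = t_abs >= cp
            if np.any(after):
                # mean continues from its value at the change point with the
                # post-treatment slope, for every population
                for pi, pop in enumerate(cfg.populations):
                    mask = after & (pop_idx == pi)
                    if np.any(mask):
                        base = pop.mean_at(np.array([cp]))[0]
                        means[mask] = base + cfg.treatment.post_slope_um3_per_min * (
                            (t_abs[mask] - cp) / 60.0
                        )
        bio = np.empty(n)
        for pi, pop in enumerate(cfg.populations):
            mask = pop_idx == pi
            bio[mask] = _lognormal_multiplier(rng, pop.cv, int(mask.sum()))
        true_vol = means * bio
        is_junk = np.zeros(n, dtype=bool)
        if cfg.noise_floor_weight > 0:
            is_junk = rng.uniform(size=n) < cfg.noise_floor_weight
            n_junk = int(is_junk.sum())
            # sub-threshold junk: uniform well below the smallest population
            true_vol[is_junk] = rng.uniform(
                0.01 * min_mean0, 0.2 * min_mean0, size=n_junk
            )
        d_true = pipeline.volume_to_diameter(true_vol)
        d_meas = d_true * (1.0 + rng.normal(0.0, cfg.measurement_cv, size=n))
        d_meas = np.maximum(d_meas, 0.0)
        meas_vol = pipeline.diameter_to_volume(d_meas)
        if fi in debris_by_file:
            meas_vol = meas_vol * (1.0 + debris_by_file[fi])
            d_meas = pipeline.volume_to_diameter(meas_vol)
        heights = np.rint(pipeline.diameter_to_height(d_meas, header)).astype(
            np.int64
        )
        first = np.maximum(heights - header.correction_factor, 0)
        pulses = np.zeros((n, 5), dtype=np.int64)
        pulses[:, 0] = first

        n_ticks = int(math.ceil(cfg.file_duration_s * 1000.0 / tick))
        edges_ms = (np.arange(1, n_ticks + 1)) * tick
        cum = np.searchsorted(t_local * 1000.0, edges_ms, side="right")
        cum[-1] = n
        section = TimeSection(edges_ms, cum, tick_width_ms=tick)
        fheader = replace(header, start_time_s=start, duration_s=cfg.file_duration_s)
        files.append(
            MeasurementFile(
                header=fheader, pulses=pulses, time_section=section, provenance="raw"
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "pulse_id": np.arange(pulse_id0, pulse_id0 + n),
                    "file_index": np.full(n, fi),
                    "true_time_s": t_abs,
                    "true_volume_um3": true_vol,
                    "measured_volume_um3": meas_vol,
                    "population": [pop_labels[i] for i in pop_idx],
                    "is_junk": is_junk,
                }
            )
        )
        pulse_id0 += n

    change_points: list[tuple[float, str]] = []
    if cfg.treatment is not None:
        change_points.append((cfg.treatment.time_s, "treatment"))
        change_points.append((cfg.treatment.change_point_s, "response"))
    for d in cfg.debris_events:
        change_points.append((d.file_index * cycle, f"debris file {d.file_index}"))
    truth = GroundTruth(
        events=pd.concat(truth_frames, ignore_index=True),
        change_points=change_points,
        config=cfg,
    )
    return files, truth


# ---------------------------------------------------------------------------
# presets emulating the study's samples

#: response lag (min) of staurosporine-treated L1210 cells detected by the
#: bilinear scan.
DRUG_RESPONSE_LAG_MIN = 9.7


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named simulation configurations emulating the study conditions.

    beads4um
        4.000 ± 0.033 µm diameter polystyrene sizing beads, no growth,
        2 h of 150 s files — the measurement-error benchmark.
    g1_arrest
        A single G1-arrested yeast-like population growing linearly.
    bimodal_arrest
        Three subpopulations (slow-growing / G1-arrested /
        metaphase-arrested) with distinct linear rates that diverge over
        a 3 h arrest.
    synchronized
        An elutriated, synchronously proliferating population with
        exponential per-cell growth and gradually desynchronising spread.
    drug_response
        An L1210-like culture: constant mean volume for 1 h, treatment at
        60 min, a 9.7 min response lag, then a linear volume decline of
        ~15 % per hour (apoptotic volume decrease).
    """
    bead_vol = pipeline.diameter_to_volume(BEAD_DIAMETER_UM)
    # volume CV ~ 3x the (small) diameter CV of the bead standard
    bead_cv = 3.0 * BEAD_DIAMETER_SD_UM / BEAD_DIAMETER_UM
    presets = {
        "beads4um": SimulationConfig(
            populations=[
                PopulationSpec(1.0, bead_vol, bead_cv, "none", 0.0, "beads")
            ],
            total_duration_min=120.0,
            measurement_cv=0.005,
            seed=seed,
        ),
        "g1_arrest": SimulationConfig(
            populations=[PopulationSpec(1.0, 30.0, 0.15, "linear", 0.3, "G1")],
            total_duration_min=120.0,
            seed=seed,
        ),
        "bimodal_arrest": SimulationConfig(
            populations=[
                PopulationSpec(0.2, 22.0, 0.10, "linear", 0.05, "SG"),
                PopulationSpec(0.5, 45.0, 0.10, "linear", 0.35, "G1"),
                PopulationSpec(0.3, 90.0, 0.10, "linear", 0.75, "M"),
            ],
            total_duration_min=180.0,
            seed=seed,
        ),
        "synchronized": SimulationConfig(
            populations=[
                PopulationSpec(1.0, 20.0, 0.12, "exponential", 0.004, "G1-sync")
            ],
            total_duration_min=240.0,
            seed=seed,
        ),
        "drug_response": SimulationConfig(
            populations=[PopulationSpec(1.0, 900.0, 0.15, "none", 0.0, "L1210")],
            total_duration_min=120.0,
            treatment=TreatmentSpec(
                time_s=3600.0,
                lag_s=DRUG_RESPONSE_LAG_MIN * 60.0,
                post_slope_um3_per_min=-0.15 * 900.0 / 60.0,
            ),
            seed=seed,
        ),
    }
    if name not in presets:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    cfg = presets[name]
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
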