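"""End-to-end batch pipeline: load -> decode -> filters -> QC -> features
-> kinetics, with every stage's outputs written to an output directory and
a manifest recording versions, seeds, and per-stage counts.

Files are decoded one at a time and reduced to event tables immediately, so
a full timecourse never needs to hold raw pulse blocks for every file in
memory at once.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, features, kinetics, pipeline, qc
from .errors import ConfigError
from .io import Timecourse, load_timecourse, write_event_csv, write_measurement_file


@dataclass
class HistogramConfig:
    bins: int = 256
    binning: str = "log"
    smoothing_bins: float = 3.0
    bound_levels: tuple = (10.0, 25.0, 33.0)


@dataclass
class KineticsConfig:
    window_length_min: float = 60.0
    step_min: float = 3.0
    breakpoint_grid_step_s: float = 30.0
    breakpoint_edge_exclusion_s: float = 300.0
    event_time_s: float | None = None


@dataclass
class RunConfig:
    """Batch-run configuration (mirrors the CLI flags 1:1)."""

    inputs: list = field(default_factory=list)
    dialect: str = "fixture"
    out_dir: str = "coultertrace_out"
    filters: pipeline.FilterConfig = field(default_factory=pipeline.FilterConfig)
    debris: qc.DebrisConfig = field(default_factory=qc.DebrisConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    run_qc: bool = True
    run_breakpoint: bool = False

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        """Build from a YAML/JSON-style keyed document; unknown keys are
        rejected."""
        doc = dict(doc)
        sections = {
            "filters": pipeline.FilterConfig,
            "debris": qc.DebrisConfig,
            "histogram": HistogramConfig,
            "kinetics": KineticsConfig,
        }
        kwargs = {}
        for key, sub_cls in sections.items():
            if key in doc:
                sub = doc.pop(key)
                _check_keys(sub, sub_cls, key)
                kwargs[key] = sub_cls(**sub)
        _check_keys(doc, cls, "run config")
        kwargs.update(doc)
        return cls(**kwargs)


def _check_keys(doc: dict, cls, where: str) -> None:
    known = set(cls.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown {where} keys: {sorted(unknown)}")


def filtered_events(
    timecourse: Timecourse,
    filters: pipeline.FilterConfig | None = None,
    histogram: HistogramConfig | None = None,
) -> pd.DataFrame:
    """Decode a timecourse and apply the standard per-file filters: the
    noise floor, then exclusion bounds at the configured bound-pair level
    of each file's own histogram."""
    filters = filters or pipeline.FilterConfig()
    histogram = histogram or HistogramConfig()
    events = pipeline.decode_timecourse_events(timecourse)
    return _exclusion_filter(events, filters, histogram)


def _exclusion_filter(
    events: pd.DataFrame,
    filters: pipeline.FilterConfig,
    histogram: HistogramConfig,
) -> pd.DataFrame:
    """Per-file noise floor then exclusion bounds at the configured level."""
    out = []
    for _, grp in events.groupby("file_index", sort=True):
        grp = pipeline.filter_noise_floor(grp, filters)
        vols = pipeline.included_volumes(grp)
        hist = features.build_histogram(
            vols,
            bins=histogram.bins,
            binning=histogram.binning,
            smoothing_bins=histogram.smoothing_bins,
        )
        bp = features.bound_pair(hist, filters.exclusion_bound_level)
        grp = pipeline.apply_exclusion_bounds(grp, bp)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full batch pipeline; returns the manifest dict.

    Stage order: load -> QC/interpolate -> decode+times -> filters ->
    features -> kinetics.  On a stage error, partial outputs are retained
    and the manifest (written last on success, or by the CLI on failure)
    marks the failed stage.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "coultertrace_version": __version__,
        "python": platform.python_version(),
        "stages": {},
    }

    tc = load_timecourse(cfg.inputs, dialect=cfg.dialect)
    manifest["stages"]["load"] = {"n_files": len(tc), "n_pulses": tc.n_pulses}

    if cfg.run_qc and len(tc) >= 3:
        tc, report = qc.clean_timecourse(tc, cfg.debris, cfg.filters)
        report.to_csv(out_dir / "qc_report.csv", index=False)
        for i, mf in enumerate(tc):
            if mf.provenance == "interpolated":
                write_measurement_file(mf, out_dir / f"interpolated_{i:04d}.txt")
        manifest["stages"]["qc"] = {
            "n_flagged": int(report["flagged"].sum()),
            "report": "qc_report.csv",
        }

    events = pipeline.decode_timecourse_events(tc)
    events = _exclusion_filter(events, cfg.filters, cfg.histogram)
    write_event_csv(events, out_dir / "events.csv")
    manifest["stages"]["events"] = {
        "n_events": len(events),
        "n_noise_excluded": int(events["noise_excluded"].sum()),
        "n_bounds_excluded": int(events["bounds_excluded"].sum()),
    }

    bound_rows = []
    for fi, grp in events.groupby("file_index", sort=True):
        vols = grp.loc[~grp["noise_excluded"], "volume_um3"].to_numpy()
        hist = features.build_histogram(
            vols,
            bins=cfg.histogram.bins,
            binning=cfg.histogram.binning,
            smoothing_bins=cfg.histogram.smoothing_bins,
        )
        row = {"file_index": fi, "mode_volume_um3": hist.mode_volume}
        for level in cfg.histogram.bound_levels:
            bp = features.bound_pair(hist, level)
            row[f"lower_{level:g}"] = bp.lower
            row[f"upper_{level:g}"] = bp.upper
        bound_rows.append(row)
    pd.DataFrame(bound_rows).to_csv(out_dir / "bound_pairs.csv", index=False)
    manifest["stages"]["features"] = {
        "n_files": len(bound_rows),
        "bound_levels": list(cfg.histogram.bound_levels),
    }

    inc = pipeline.included_events(events)
    series = kinetics.windowed_growth_rate(
        inc["time_s"].to_numpy(),
        inc["volume_um3"].to_numpy(),
        window_length_min=cfg.kinetics.window_length_min,
        step_min=cfg.kinetics.step_min,
    )
    series.to_frame().to_csv(out_dir / "growth_rates.csv", index=False)
    manifest["stages"]["rates"] = {"n_windows": int(series.window_centers_s.size)}

    if cfg.run_breakpoint:
        result = kinetics.bilinear_breakpoint(
            inc["time_s"].to_numpy(),
            inc["volume_um3"].to_numpy(),
            event_time_s=cfg.kinetics.event_time_s,
            grid_step_s=cfg.kinetics.breakpoint_grid_step_s,
            edge_exclusion_s=cfg.kinetics.breakpoint_edge_exclusion_s,
        )
        result.to_frame().to_csv(out_dir / "sse_curve.csv", index=False)
        manifest["stages"]["breakpoint"] = {
            "best_time_s": result.best_time_s,
            "significant": bool(result.significant),
            "lag_after_event_min": result.lag_after_event_min,
        }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
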