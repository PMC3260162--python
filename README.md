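# coultertrace

Continuous, long-term cell-volume timecourses from a commercial Coulter
counter: decode instrument pulse files into single-particle (time, volume)
events, stitch multi-file recordings onto one time axis, clean them,
extract histogram features and subpopulation tracks, and quantify growth
rates and rate-change points.

## Who this is for

A Coulter counter (e.g. a Beckman-Coulter Multisizer) measures particle
volume via the resistive-pulse principle: a particle transiting the
aperture lowers its conductivity in proportion to particle volume,
producing a pulse whose height encodes size. Operated back-to-back —
one 150 s file per measurement, separated by aperture flushes — it can
record millions of single-cell volumes over several hours of live culture.
The commercial software, however, resets each file's clock to zero and
caps per-file exports, so multi-hour growth-rate analysis needs dedicated
batch tooling. This package is that tooling, for anyone measuring cell
size dynamics (cell-cycle arrest, synchronized growth, drug response) in
suspension culture with such an instrument, plus a seeded simulator so the
entire analysis chain can be developed and validated without hardware.

## The analysis in brief

**Decoding.** Pulse height *h* (counts) is the file's correction factor
plus the first of the five per-pulse values. The spherical-equivalent
(Heywood) diameter follows from the header calibration constants

```
d = Kd · (gain · h / (current · countspervolt))^(1/3),   countspervolt = 838 870 V⁻¹
```

and volume is v = π/6·d³. Per-pulse times do not exist in the raw file:
every 200 ms the instrument logs elapsed time and the cumulative pulse
count, and the m pulses within one tick are linearly distributed across
it, giving every event ≤ 200 ms time error.

**Cleaning.** Per file, the lowest 2 % of events by volume are flagged as
instrument noise, and events outside the file's 10 % *bound pair* — the
volumes where the smoothed histogram crosses 10 % of its mode count on
each side — are excluded from rate analysis. A file whose 25 % bound pair
exceeds 1.025× the corresponding bound of its neighboring files is a
*debris file* (partial aperture occlusion) and is replaced by quantile
interpolation between its clean neighbors.

**Kinetics.** Growth rate is the OLS slope of volume (µm³) on time (min)
over all included single-particle events in a moving window (default
60 min, stepped 3 min) with a t-based 95 % CI. A rate-change point is
located with a bilinear model: split the events at a candidate time, fit
an independent line to each side, and scan the total sum of squared
errors (SSE) over a 30 s grid — the SSE minimum marks the change point,
and its offset from a known event time (e.g. drug addition) is the
response lag. Bound and mode trajectories can be compared against linear
(y = ax+b) and exponential (y = A·e^(bx)) growth laws by R² on the
original scale.

## Worked example

```python
import numpy as np
import coultertrace as ct

# simulate an L1210-like drug-response experiment: constant volume for
# 60 min, treatment at 60 min, 9.7 min lag, then decline (~15 %/h)
files, truth = ct.generate_timecourse(ct.preset("drug_response", seed=0))
events = ct.included_events(ct.filtered_events(ct.timecourse_from_files(files)))
result = ct.bilinear_breakpoint(
    events.time_s.to_numpy(), events.volume_um3.to_numpy(),
    event_time_s=3600.0, grid_step_s=30.0,
)
print(f"detected lag: {result.lag_after_event_min:.2f} min")
print(f"SSE reduction: {100 * result.sse_reduction:.2f}% "
      f"(significant: {result.significant})")
```

prints

```
detected lag: 9.00 min
SSE reduction: 2.34% (significant: True)
```

i.e. the scan recovers the simulated 9.7 min response lag to within one
30 s grid step of estimator scatter, and the bilinear fit improves on a
single line by well over the 1 % significance threshold (a mock-treated,
constant-volume control stays below it). The `examples/` directory holds
one short script per capability — decoding and stitching, filters and
bound pairs, debris QC, growth rates, breakpoints, subpopulation tracking
and growth-model comparison — each printing the numbers it computes.

A thin CLI mirrors the library for batch use:

```bash
coultertrace simulate --preset beads4um --seed 1 --out-dir data/
coultertrace convert data/beads4um_*.txt --out events.csv
coultertrace rates events.csv --window 60 --step 3 --out rates.csv
coultertrace qc data/beads4um_*.txt --ratio 1.025 --level 25 --out-dir qc/
```

## Layout

```
src/coultertrace/
  io.py        instrument-file reading/writing, timecourse stitching
  pipeline.py  pulse decoding, timestamp assignment, event filters
  features.py  histograms, bound pairs, subpopulation tracking, colormaps
  qc.py        debris-file detection and interpolation
  kinetics.py  windowed growth rates, bilinear breakpoints, model fits
  simulate.py  seeded instrument-style simulator with ground truth
  workflow.py  end-to-end batch pipeline with manifest
  cli.py       command-line front end
docs/methods.md   model, parameters, and design notes
examples/         narrative scripts, one per capability
```
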