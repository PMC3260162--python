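# Methods

This note records the models, parameter choices and numerical conventions
behind `coultertrace`, and what the simulator does and does not emulate.

## Instrument model and decoding

A resistive-pulse (Coulter) instrument reports, per 150 s recording, a
header of calibration constants, five integers per particle pulse, and a
time section logging elapsed milliseconds and cumulative pulse count every
200 ms. Only the first per-pulse integer is interpreted: pulse height =
correction factor + value[0], clamped at zero (a pulse cannot have
negative amplitude); the remaining four values are stored verbatim and
unused. Height converts to the Heywood (spherical-equivalent) diameter

d = Kd · (gain · h / (current · countspervolt))^(1/3),
countspervolt = 838 870 V⁻¹,

which is strictly increasing with d(0) = 0, and volume is π/6·d³ (µm³
throughout). Every constant is taken from the file header, so a vendor
calibration variant can be swapped in behind the same interface without
touching any downstream module — everything after decoding consumes
volumes only.

The canonical on-disk format is a plain-text fixture dialect carrying
exactly the fields above (header key/values, a five-integer pulse table, a
time-section table, and a provenance flag distinguishing raw from
interpolated files). Floats are serialized at full repr precision so
read∘write is the identity field-for-field. The native binary `.#m4`
layout is reserved behind a `dialect="native-adapter"` hook. A per-file
cap of 525 000 pulses is enforced on write, matching the commercial
software's file limit.

**Timestamp assignment.** The m pulses recorded in tick (t_{k-1}, t_k]
receive times t_{k-1} + j·(t_k − t_{k-1})/m, j = 1..m; a single pulse
lands at the tick's end. Any assigned time is within one tick width
(200 ms) of the true arrival, which the test suite verifies against
simulator ground truth. Multi-file stitching re-anchors every file on the
earliest file's start time; flush gaps between files are preserved, never
compressed, and overlapping recording intervals are rejected.

## Event filters

Per file, exactly floor(0.02·N) events — the smallest by volume, ties
broken by record order — are flagged as instrument noise, and events
outside the file's exclusion bound pair (default level 10 % of the mode)
are flagged out of rate analysis. The interval is closed: events exactly
on a bound are retained. Filters flag rather than delete so that colormap
displays can still show the full distribution with the bounds drawn as
overlays; both filters are idempotent and order-preserving.

## Histograms and bound pairs

Default binning is 256 log-spaced bins spanning the included-data range —
log spacing suits multiplicative size noise — smoothed with a Gaussian
kernel of 3 bins bandwidth. The mode is the midpoint of the smoothed-count
argmax bin (ties → lowest volume); no sub-bin refinement is applied, for
testability. One consequence of log binning worth knowing: the count
maximum estimates the mode of the density with respect to log volume
(exp(µ) for a log-normal), not the linear-scale density mode
exp(µ − σ²); with σ ≈ 0.1–0.15 the difference is ~1–2 %.

A bound pair at level X is the pair of volumes where the smoothed counts
cross X % of the mode count, one on each side of the mode. Crossings are
taken nearest the mode (the bracketing crossings, not the outermost),
linearly interpolated between bin midpoints; an exact hit returns that
midpoint, and a side with no crossing returns the data extremum with a
clamped flag. Level 100 returns the mode on both sides. Bounds are
computed on smoothed counts by default (raw counts available by flag).

Subpopulation modes are local peaks of the smoothed counts with
prominence ≥ 5 % of the global maximum and ≥ 10 bins separation; closer
peaks merge. Events are assigned to the region delimited by the
smoothed-count minima between adjacent peaks (a boundary-valued event
goes to the lower-volume track). Peaks are associated across files by
greedy nearest-neighbor matching with a 15 % maximum relative jump per
file; unmatched peaks start new tracks, and a track that misses a file
records a gap but stays matchable. Colormap matrices normalize each time
column to sum to 1 (the relative fraction of particles per measurement);
empty columns stay zero.

## Debris QC and interpolation

A partially occluded aperture inflates the apparent size distribution for
one or a few files until a flush clears it. A file is flagged when its
25 % bound pair (upper member by default — occlusions inflate the
large-volume tail) is at least 1.025× the corresponding bound of its
neighbors. Two deliberate conventions:

- **Neighbor rule.** The default requires exceeding the threshold against
  *both* neighbors. A steadily growing culture gains ~2–3 % volume per
  200 s file cycle, so a one-neighbor ("either") rule would false-flag
  healthy monotone growth; "both" targets the transient single-file
  spikes the criterion exists to remove. The literal one-neighbor reading
  is available by config — and is the right choice when *runs* of
  consecutive corrupted files are expected, which the "both" rule cannot
  see (each run member matches its equally inflated neighbor).
- **Threshold comparison.** The comparison is inclusive at the threshold
  within a 1e-9 relative tolerance, so a file sitting exactly at the
  1.025 criterion is flagged deterministically rather than at the mercy
  of floating-point rounding.

The first and last files, having one neighbor, are never flagged.
Cleaning aborts when more than half the files are flagged (persistent
occlusion is not an interpolation problem). A flagged file is rebuilt
from its nearest clean neighbors: pulse count = round(weighted mean of
the neighbors' included counts); volume_j mixes the neighbors' j/(m+1)
empirical quantiles (weights 0.5/0.5 for an isolated file,
time-proportional across a run of consecutive flagged files); timestamps
are spaced evenly across the replaced file's full duration, with volumes
laid out by a fixed stride permutation so size does not correlate with
time within the file. Replacements carry provenance "interpolated" and
are written as new files; originals are never modified.

## Kinetics

Growth rates are OLS slopes of volume on time-in-minutes over all
included single-particle events in each window (default 60 min length,
3 min step) — not over per-file summary statistics — with 95 % CIs from
the standard slope-error formula and the t quantile. Windows with fewer
than two distinct event times yield NaN. Slopes and CIs agree with an
independent normal-equations oracle to 1e-9 relative.

The bilinear change-point scan computes, for each candidate split time on
a grid (default: every 30 s, excluding 5 min at each edge where one-sided
fits are unstable), the SSE of an OLS line fit to events before the split
plus that of a line fit at/after it, using prefix sums for O(n + grid)
total cost. The argmin (ties → earliest) is the change point; candidates
with fewer than two distinct times on a side are skipped. The two lines
are fit independently (no continuity constraint at the split; a
constrained variant reduces estimator variance when the truth is a
continuous kink, but the unconstrained form is the method's definition
here). Significance requires the relative SSE reduction versus a single
global line to exceed 1 % — a pragmatic default for distinguishing a real
change from the always-nonnegative improvement of the richer model, not a
formal test. Results are invariant to input event order.

Growth-model comparison fits y = ax+b by OLS and y = A·e^(bx) by
nonlinear least squares on the original scale (initialized from a
log-linear fit; the log-linear estimate is reported with a flag on
non-convergence), with R² = 1 − SS_res/SS_tot computed on the original
scale for both so the two numbers are directly comparable.

## Simulator

The simulator emulates the recording geometry (150 s files separated by
50 s flush gaps, i.e. the ~75 % duty cycle of back-to-back measurement;
Poisson pulse counts; uniform arrival times; 200 ms time sections) and
the population structure of the studied samples: one or more populations
with log-normal biological size spread (mean-preserving, CV as
configured) around a time-dependent mean following a constant, linear
(µm³/min) or exponential (1/min) growth law. Instrument noise is
multiplicative Gaussian on the measured diameter. Generated volumes are
encoded to integer pulse heights by inverting the calibration, so
simulator output exercises the full decoding path; quantization keeps
encoded-then-decoded volumes within ~1e-6 relative of the generated ones
at realistic heights.

Artifacts: a configurable fraction of sub-threshold junk events (uniform
well below the smallest population mean) emulates the electronic noise
floor; a debris event inflates every measured volume of one file by
(1+inflation), modelling the raised baseline resistance of a partial
occlusion — this makes the injected bound inflation exact by
construction; a treatment switches the mean-volume trajectory to a new
linear slope after a configurable lag.

Presets pin the study conditions: `beads4um` (4.000 µm beads with 0.033 µm
diameter SD, no growth, 2 h — the measurement-error benchmark),
`g1_arrest` (single population, linear growth 0.3 µm³/min from 30 µm³),
`bimodal_arrest` (slow-growing/G1/M-like populations with weights
0.2/0.5/0.3 and distinct linear rates), `synchronized` (exponential
growth at 0.004 min⁻¹ from 20 µm³ over 4 h), and `drug_response`
(L1210-like 900 µm³ population, constant for 60 min, treated at 60 min,
9.7 min response lag, then −2.25 µm³/min ≈ 15 %/h decline, CV 15 %).
Presets default to 20 000 pulses per file — a desk-scale density chosen
so full pipelines run in seconds; real recordings typically carry several
times more. All randomness flows from a single seeded generator in
documented order, making output byte-identical for a fixed seed.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: aperture physics (off-axis particle paths,
pulse-shape effects, coincidence), non-spherical particle orientation
error, electrolyte drift, the commercial software's flush/unblock timing,
and mechanistic cell-cycle structure (budding, division). Populations are
i.i.d. draws around a deterministic mean trajectory; real cultures have
persistent per-cell identities and correlated dynamics, and a treated
culture's variance change (visible in real drug-response data) is not
modelled.

## Operating characteristics worth knowing

- The bead preset's windowed-rate scatter is far below the 0.111 µm³/min
  three-SD resolution bound measured on real bead data, because the
  simulator omits the slow instrument drifts that dominate real
  measurement error; the acceptance check is therefore a one-sided bound,
  not a reproduction of the real error magnitude.
- Under the drug-response conditions the unconstrained bilinear estimator
  recovers the lag with a per-run SD of roughly 1.5 min and a slight
  early tendency (a few tenths of a minute) from the asymmetric segment
  lengths; the median over 10 runs typically lands within half a minute
  of the true lag.
- Debris detection is threshold-sharp: injected single-file bound shifts
  of >2.5 % are flagged at realistic per-file counts, shifts ≤1.5 % are
  not, and the flag transition sits exactly at the configured 1.025
  ratio.

## Known limitations

Bit-exact parsing of vendor binary files is out of scope until the byte
layout is transcribed into the native adapter. No coincidence correction
or pulse-width-based rejection of off-axis particles is applied. The
subpopulation decomposition is peak/valley-based, not a mixture model; it
merges components closer than the separation threshold and assigns events
deterministically at boundaries. Breakpoint analysis fits exactly two
segments; multi-phase responses need repeated application or a different
tool.
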