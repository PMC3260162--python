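"""Moving-window growth rates: measurement error vs real growth.

Growth rate is the OLS slope of single-particle volume on time over a
60 min window shifted every 3 min.  Non-growing beads calibrate the
method's resolution; a linearly growing arrested population shows a clear
positive rate with tight confidence intervals.
"""

import numpy as np

import coultertrace as ct


def rates_for(preset_name, seed):
    files, _ = ct.generate_timecourse(
        ct.preset(preset_name, seed=seed, pulses_per_file=8000)
    )
    events = ct.included_events(ct.filtered_events(ct.timecourse_from_files(files)))
    return ct.windowed_growth_rate(
        events.time_s.to_numpy(), events.volume_um3.to_numpy(),
        window_length_min=60, step_min=3,
    )


beads = rates_for("beads4um", seed=0)
print("beads (no growth):")
print(f"  mean rate {np.nanmean(beads.slopes_um3_per_min):+.4f} um^3/min, "
      f"SD {np.nanstd(beads.slopes_um3_per_min):.4f}")
print(f"  3-SD resolution bound: "
      f"{3 * np.nanstd(beads.slopes_um3_per_min):.4f} um^3/min")

yeast = rates_for("g1_arrest", seed=0)
print("\nG1-arrested population (true rate 0.30 um^3/min):")
print(f"  mean rate {np.nanmean(yeast.slopes_um3_per_min):+.4f} um^3/min, "
      f"mean 95% CI half-width {np.nanmean(yeast.ci95_half):.4f}")
# The bead rate scatter is pure measurement error; a biological rate well
# above the 3-SD bead bound is resolvable growth.
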