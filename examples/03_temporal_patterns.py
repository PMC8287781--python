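"""Trajectory pattern labels and peak-change analysis.

Classifies each gene's DE time-point sets across d3/d7/d28 into canonical
pattern labels, then finds the time point(s) of peak change by pairwise
injured-vs-injured contrasts (conditional FDR): a DE time point survives
into the peak set unless another DE time point significantly exceeds it in
the gene's direction.
"""

import tempodeg as td

sim = td.simulate_panel(seed=1)
res = td.analyze_counts(sim.count_table, sim.samples)

profiles = res.vehicle_profiles
print("pattern label tallies (vehicle arm):")
print(profiles["pattern_label"].value_counts().head(8).to_string())

tally = td.peak_set_tally(profiles, "consistent_up")
print("\npeak sets among consistently upregulated genes:")
print(tally.to_string())
# 'd3+d7' marks genes whose change peaks acutely; 'd3+d7+d28' genes show no
# significant difference between time points and peak everywhere.

rec = td.recovery_metrics(sim.truth, profiles, vehicle_results=res.vehicle_results)
print(f"\nplanted-label recovery among DE-detected genes: {rec['pattern_overall']:.2f}")
print(f"planted-peak-set recovery:                       {rec['peak_overall']:.2f}")
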