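"""Categorize how complement inhibition reshapes each gene's trajectory.

Compares each gene's vehicle-arm DE time-point set V with its treated-arm
set C: inhibited (V≠∅, C=∅), induced (V=∅, C≠∅), shortened (C⊊V),
extended (V⊊C), shifted, or unchanged. Separately tests, per time point,
whether treatment changed the expression *level* among genes that stayed
DE (treated-vs-vehicle contrast, conditional FDR), and embeds all samples
by PCA.
"""

import tempodeg as td

sim = td.simulate_panel(seed=1)
res = td.analyze_counts(sim.count_table, sim.samples)

print("treatment-effect categories:")
print(res.records["pattern_effect"].value_counts().to_string())

reduced_d7 = td.reduced_among_remaining_up(
    res.level_tests["d7"], res.vehicle_results["d7"], res.treated_results["d7"]
)
print(f"\ngenes still upregulated at d7 whose level treatment reduced: {len(reduced_d7)}")

print("\nastrocyte/microglia marker classes with reduced levels:")
print(res.marker_table[["marker_class", "n_on_panel", "n_reduced"]].to_string(index=False))
# A1 (neurotoxic) markers respond more strongly than A2 (trophic) markers.

coords = res.pca_coords
print(f"\nPCA: PC1 explains {res.pca_evr[0]:.1%}, PC2 {res.pca_evr[1]:.1%} of variance")
print("mean PC1 by group (treated day-7 samples sit closer to recovery):")
merged = coords.join(sim.samples.set_index("sample_id"))
print(merged.groupby(["treatment", "timepoint"])["PC1"].mean().round(1).to_string())
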