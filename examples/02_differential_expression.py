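"""Two-group differential expression with the two FDR variants.

Contrasts injured (vehicle, day 7) against sham on log2 normalized counts:
Welch t-test per gene, signed fold change, and either standard
Benjamini-Hochberg FDR or the conditional variant (BH restricted to genes
with raw p < 0.05, used for low-powered chronic/injured-vs-injured
comparisons). A gene is DE iff FDR < 0.05 — no fold-change cutoff.
"""

import tempodeg as td

sim = td.simulate_panel(seed=1)
norm, _ = td.normalize_counts(sim.count_table)
endo = norm.loc[sim.count_table.genes_of_class("Endogenous")]

test = {"group": "TBI", "timepoint": "d7", "treatment": "vehicle"}
ref = {"group": "sham"}

for mode in ("standard", "conditional"):
    res = td.compare_groups(endo, sim.samples, test=test, ref=ref, fdr_mode=mode)
    n_up = (res["direction"] == "up").sum()
    n_down = (res["direction"] == "down").sum()
    print(f"{mode:>12} FDR: {n_up} up, {n_down} down at FDR < 0.05")

res = td.compare_groups(endo, sim.samples, test=test, ref=ref)
top = res.nlargest(5, "fc_signed")[["gene_id", "fc_signed", "p_value", "fdr"]]
print("\nstrongest upregulation at day 7 (signed fold change ≈ 2^3 = 8 for")
print("planted log2FC = 3 effects):")
print(top.round(4).to_string(index=False))
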