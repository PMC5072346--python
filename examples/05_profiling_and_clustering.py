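"""Descriptive methylome profiling of the simulated study.

State binning (LMS / PMS / HMS), annotation-stratified summaries,
average-linkage clustering of samples with a newick tree, and replicate
concordance.
"""

import pandas as pd

from pdxmeth.pipeline import run_simulated_pipeline
from pdxmeth.preprocess import beta_to_m
from pdxmeth.profile import (
    annotation_summary,
    classify_states,
    cluster_samples,
    cut_tree_k,
    replicate_concordance,
)
from pdxmeth.synthetic import SimulationDesign

sim, result = run_simulated_pipeline(SimulationDesign(n_probes=8_000, seed=42))
sheet = sim.samples

f0 = list(sheet.select(generation="F0", model="PDX36"))
dac = list(sheet.select(treatment="DAC", model="PDX36"))
binning = classify_states(result.beta_norm[f0 + dac])
print("state fractions (LMS <0.2, PMS 0.2-0.7, HMS >0.7):")
print(binning.fractions.round(3).to_string())
print("mean beta per sample:")
print(binning.mean_beta.round(3).to_string())

labels = {s: ("DAC" if s in dac else "F0") for s in f0 + dac}
summ = annotation_summary(result.beta_norm[f0 + dac], sim.manifest, "cgi_relation", labels)
print("\nmean beta by CpG-island relation (F0 vs DAC-treated):")
print(summ.table.xs("mean", axis=1, level=1).round(3).to_string())

keep = [s for s in sheet.select(treatment="none", species="human")
        if sheet.df.loc[s, "model"] != "SKOV3"]
tree = cluster_samples(result.beta_norm[keep], "hierarchical_average")
clusters = cut_tree_k(tree.linkage_matrix, keep, k=3)
purity = pd.crosstab(sheet.df.loc[keep, "model"], clusters).max(axis=0).sum() / len(keep)
print(f"\nhierarchical clustering cut at k=3: cluster purity by model = {purity:.2f}")

reps = list(sheet.select(model="PDX36", generation="F3", treatment="none"))
r, _ = replicate_concordance(beta_to_m(result.beta_norm[reps]), reps)
print(f"replicate concordance (pairwise Pearson r on M-values): "
      f"{r.values[0, 1]:.3f}, {r.values[0, 2]:.3f}, {r.values[1, 2]:.3f}")
print("\nDAC lowers mean beta mostly by depleting the HMS state; untreated "
      "samples cluster by xenograft model, and biological replicates stay "
      "near-perfectly correlated.")
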