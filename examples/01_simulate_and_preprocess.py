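"""Simulate a PDX methylome study and run the preprocessing cascade.

Generates a 450K-like dataset (trimodal beta landscape, type-II probe
compression, batch effects, mouse cross-reactive probes), then applies
detection filtering, mouse-probe masking, annotation exclusions, BMIQ
normalization and batch adjustment, printing the probe accounting at
each stage.
"""

from pdxmeth import batch_adjust, beta_to_m, bmiq_normalize, compute_beta
from pdxmeth.preprocess import detection_filter, exclude_probes, mouse_mask
from pdxmeth.synthetic import SimulationDesign, simulate_dataset

design = SimulationDesign(n_probes=8_000, seed=42)
sim = simulate_dataset(design)
print(f"simulated {design.n_probes} probes x {len(sim.samples)} samples "
      f"({len(sim.samples.human_samples)} human, 1 mouse control)")

data, r1 = detection_filter(sim.intensities, sim.samples)
data, r2 = mouse_mask(data, sim.samples)
data, r3 = exclude_probes(data, sim.manifest)
report = r1.merge(r2).merge(r3)
print("\nfilter cascade (probes removed per stage):")
print(report.to_frame().to_string(index=False))

beta = compute_beta(data.meth, data.unmeth)  # beta = M / (M + U + 100)
beta_norm, model = bmiq_normalize(beta, sim.manifest)
m_adj = batch_adjust(beta_to_m(beta_norm), sim.samples.df.loc[beta.columns, "batch"])
n_conv = sum(v["converged"] for v in model.per_sample.values())
print(f"\nBMIQ: {n_conv}/{len(model.per_sample)} samples converged")
print(f"adjusted M matrix: {m_adj.shape[0]} probes x {m_adj.shape[1]} samples")
print("\nThe retained probe count is the analysis universe every downstream "
      "stage (contrasts, screening, profiling) operates on.")
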