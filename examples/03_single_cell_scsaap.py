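"""Pseudo-bulk single-cell APA (scSAAP) on planted trophoblast subtypes.

Simulated placental cells carry a 69-gene-style marker panel (23 markers
per subtype) and a programmed long-isoform fraction per subtype: SCT
0.25, EVT 0.40, VCT 0.50. The analysis assigns clusters to subtypes by
marker score, splits each subtype into near/far halves along the marker
gradient, aggregates cells to pseudo-bulk, and computes centered REDs.
"""
import numpy as np

from scapa.single_cell import scsaap
from scapa.synthetic import SimConfig, simulate_cells, simulate_genome

cfg = SimConfig(seed=3, n_genes=150)
genome = simulate_genome(cfg)
sim = simulate_cells(genome)
print(f"{len(sim.counts)} cells x {sim.counts.shape[1]} genes, "
      f"{len(sim.panel)} marker genes")

res = scsaap(sim.counts, sim.region_counts, sim.panel, sim.clusters)
acc = (res.assignments["subtype"] == sim.cell_truth["subtype"]).mean()
print(f"subtype assignment accuracy vs planted truth: {acc:.1%}")
print("\nper-subtype pseudo-bulk APA (centered median RED; more negative")
print("= shorter 3'UTRs than the cohort average):")
print(res.summary[["n_cells", "n_genes", "centered_red"]].to_string())

diff = (res.summary.loc["SCT", "median_red"]
        - res.summary.loc["VCT", "median_red"])
expected = np.log2(0.25 / 0.75) - np.log2(0.50 / 0.50)
print(f"\nSCT - VCT RED difference: {diff:+.3f} "
      f"(analytic from programmed psi: {expected:+.3f})")

split = scsaap(sim.counts, sim.region_counts, sim.panel, sim.clusters,
               split=True)
s = split.summary["median_red"]
print("\nnear/far split (far = more differentiated by marker score):")
for g in ["SCT_near", "SCT_far", "VCT_near", "VCT_far"]:
    print(f"  {g:9s} median RED {s[g]:+.3f}")
print("SCT far < SCT near: differentiation deepens 3'UTR shortening "
      "(the generator's psi gradient).")
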