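"""Tetramer enrichment, GO filtering, USPS construction, shift tests.

Sequence sets with a planted U-rich motif stand in for the aUTRs of
shortening-regulated genes; a toy ontology demonstrates the
hypergeometric test with the generic-term (>1000 genes) and 75%-overlap
redundancy filters; USPS-style genes are the common-upregulated genes
annotated to the top terms.
"""
import numpy as np
import pandas as pd

from scapa.enrichment import (define_usps, enrichment_correlation,
                              geneset_shift, go_enrich, tetramer_enrichment,
                              to_rna)
from scapa.synthetic import simulate_sequences

# --- tetramers: planted TTTT (UUUU on the transcript) ---
autr_regulated = simulate_sequences(80, 120, seed=5, motif="TTTT",
                                    planted_fraction=0.9, copies=2)
autr_other = simulate_sequences(80, 120, seed=6)
scores = tetramer_enrichment(autr_regulated, autr_other)
top = scores["score"].sort_values(ascending=False).head(3)
print("top tetramers enriched in regulated aUTRs (signed -log10 p):")
for kmer, s in top.items():
    print(f"  {to_rna(kmer)}  {s:+.2f}")

# the same motif drives a second comparison with flipped orientation
unstable_vs_stable = tetramer_enrichment(autr_other, autr_regulated)
r = enrichment_correlation(scores, unstable_vs_stable)
print(f"correlation of the two enrichment profiles: r = {r:+.2f} "
      f"(negative: the shared motif points opposite ways)")

# --- GO with filters ---
rng = np.random.default_rng(7)
universe = [f"g{i}" for i in range(1500)]
secreted = set(universe[:40])
term_map = {
    "secretion": secreted | set(universe[40:45]),
    "secretion_child": secreted | set(universe[60:68]),  # >75% shared genes
    "generic": set(universe[:1100]),                     # >1000 genes
    "unrelated": set(rng.choice(universe, 50, replace=False)),
}
res = go_enrich(secreted, universe, term_map)
print("\nGO table (kept flag after generic/redundancy filters):")
print(res[["n_genes", "overlap", "p_value", "kept"]].to_string())

# --- USPS-style intersection set ---
up_a = set(universe[:50]) | set(universe[200:220])
up_b = set(universe[:50]) | set(universe[300:330])
de_a = pd.DataFrame({"call": ["up" if g in up_a else "unchanged"
                              for g in universe]}, index=universe)
de_b = pd.DataFrame({"call": ["up" if g in up_b else "unchanged"
                              for g in universe]}, index=universe)
usps = define_usps(de_a, de_b, term_map, n_top_terms=3)
print(f"\nUSPS-style set: {len(usps.common_up)} genes up in both models, "
      f"{len(usps.genes)} also annotated to the top terms "
      f"{list(usps.top_terms)}")

# --- distribution shift of a per-gene statistic in a set ---
values = pd.Series(rng.normal(0, 1, len(universe)), index=universe)
values.loc[list(usps.genes)] += 0.8
shift = geneset_shift(values, usps.genes)
print(f"\nshift of the statistic in the USPS set vs other genes: "
      f"K-S p = {shift.ks_p:.2g}, Wilcoxon p = {shift.wilcoxon_p:.2g}, "
      f"direction {'+' if shift.direction > 0 else '-'}")
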