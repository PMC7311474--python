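"""Isoform stability from a metabolic-labeling (4sU) pulse.

A 1-hour 4sU pulse marks newly made RNA. The Stability Score,
log2(steady-state RPM / labeled RPM), grows with half-life:
score = -log2(1 - 2^(-t/t_half)) + constant. The generator programs
long-3'UTR isoforms with shorter half-lives, the deficit growing with
aUTR length, so long-minus-short score differences are negative and
deepen across aUTR-size bins.
"""
import numpy as np
from scipy.stats import spearmanr

from scapa.stability import (contrast_isoforms, expected_score,
                             stability_by_autr, stability_score)
from scapa.synthetic import SimConfig, simulate_4su, simulate_genome

cfg = SimConfig(seed=4, n_genes=400)
genome = simulate_genome(cfg)
records = stability_score(simulate_4su(genome))

short = records[records["isoform"] == "short"].set_index("gene_id")["score"]
rho = spearmanr(genome.truth["t_half_short"],
                short.reindex(genome.truth.index)).statistic
print(f"scored {len(records)} isoforms in {genome.truth.shape[0]} genes")
print(f"Spearman rho (programmed half-life vs score): {rho:.3f} -- the "
      f"score is a faithful monotone readout of stability")

t_half = 1.0
print(f"closed form at t_half = 1 h, 1 h pulse: score = "
      f"{expected_score(t_half):.2f} + constant (half the pool is labeled)")

contrasts, tally = contrast_isoforms(records)
print(f"\nlong-vs-short contrasts: {tally.n_long_less_stable} genes with the "
      f"long isoform significantly less stable vs "
      f"{tally.n_short_less_stable} the other way "
      f"(ratio {tally.ratio if tally.n_short_less_stable else float('inf'):.1f})")

bins, p = stability_by_autr(contrasts, genome.truth["autr_len"], seed=4)
meds = ", ".join(f"{m:+.2f}" for m in bins["median"])
print(f"median score difference by aUTR-size bin (1=shortest): {meds}")
print(f"Wilcoxon p bin1 vs bin5: {p:.3g} -- longer aUTRs carry more "
      f"destabilizing sequence, so the long-isoform penalty grows")
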