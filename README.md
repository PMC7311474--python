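# scapa

Alternative polyadenylation (APA) analysis for bulk 3ʹ-end sequencing,
conventional RNA-seq, and aggregated single-cell data — with
metabolic-labeling stability scores and the motif/gene-set statistics
needed to interpret global 3ʹUTR shortening.

Most mammalian genes carry several polyadenylation sites (PASs), so one
gene expresses mRNA isoforms differing in 3ʹUTR length; some genes also
carry intronic PASs whose use truncates the coding sequence (IPA).
Differentiation programs shift isoform usage globally — secretory
lineages such as syncytiotrophoblast or plasma cells shorten 3ʹUTRs
genome-wide, which removes destabilizing 3ʹUTR elements and stabilizes
transcripts. `scapa` is a toolkit for quantifying such shifts: it is
aimed at computational biologists who have aligned 3ʹ-end reads, RNA-seq
region counts, or single-cell count matrices and want tested, seedable
APA statistics rather than one-off scripts.

## The statistic

The central quantity is the **Relative Expression Difference (RED)**,
the between-sample change of a within-gene log2 isoform ratio:

* 3ʹ-end sequencing — the two most abundant last-exon isoforms of each
  gene, proximal (pPAS) and distal (dPAS):

  `RED = log2(dPAS/pPAS)_test − log2(dPAS/pPAS)_ref`

* RNA-seq — reads in the constitutive UTR (cUTR, stop codon → proximal
  PAS, covered by all isoforms) versus the alternative UTR (aUTR,
  proximal → distal PAS, covered only by long isoforms):

  `RED = log2(aUTR/cUTR)_test − log2(aUTR/cUTR)_ref`

Within-gene ratios cancel depth and region length, so the RNA-seq RED
estimates Δlog2 ψ (ψ = long-isoform fraction); negative RED means 3ʹUTR
shortening. Counts get a 0.5 pseudocount inside logs; significance comes
from Fisher's exact test on raw counts (unreplicated) or a Welch t-test
on per-replicate log ratios, with a >5% isoform-fraction change required
by default. The same machinery compares intronic vs terminal-exon PAS
reads (IPA activation), pseudo-bulk single-cell groups (scSAAP), and
total vs 4sU-labeled fractions (Stability Score =
log2(steady-state/newly-made RPM), a monotone readout of half-life).

## Worked example

`examples/01_bulk_3reads_apa.py` simulates a 300-gene genome with a
programmed global shortening trend (median true RED −0.15) and runs the
full 3ʹ-end path:

```
reads: 629911 aligned, 570013 PAS reads (29987 low MAPQ, 29911 <2 tail Ts)
clusters: 684 poly(A) site clusters (300 genes x 2 UTR sites + intronic sites)
3'UTR APA: 300 genes; 116 shortened vs 40 lengthened (ratio 2.9) -- a
ratio > 1 means global shortening in the test condition
median RED -0.185 (programmed -0.179; negative = shorter 3'UTRs)
```

Reads with fewer than two non-genomic tail Ts (internal-priming
artifacts) and low-MAPQ alignments are discarded; surviving cleavage
positions cluster within 24 nt; each gene's top-2 isoforms yield a RED,
a Fisher p-value and a direction call. The recovered median RED −0.185
matches the programmed cohort median −0.179 — the shortened:lengthened
ratio of 2.9 is what a −0.15 median shift with gene-to-gene spread looks
like after significance filtering. `examples/03_single_cell_scsaap.py`
shows the same statistics on pseudo-bulk single cells: subtypes are
assigned from a 69-gene marker panel at 100% accuracy, and the
secretory subtype's centered RED (−0.88) sits log2-odds-style below the
others, recovering the programmed SCT-vs-VCT difference of −1.585
within 0.04. The other examples cover RNA-seq REDs with bootstrap SDs,
stability scoring, motif/GO machinery, and the one-call pipeline.

A thin CLI wraps the same functions (`scapa cluster`, `scapa red3`,
`scapa redrna`, `scapa ipa`, `scapa bins`, `scapa de`, `scapa
stability`, `scapa scsaap`, `scapa tetramer`, `scapa go`, `scapa
simulate`, `scapa run`); every stochastic command takes `--seed`.

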