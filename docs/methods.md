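# Methods

`scapa` quantifies alternative polyadenylation (APA) — the choice among a
gene's cleavage/polyadenylation sites (PASs) — from 3ʹ-end sequencing and
from conventional RNA-seq, extends the same statistics to aggregated
single-cell data, scores isoform stability from a metabolic-labeling
pulse, and provides the motif and gene-set machinery used to interpret
the results. This note records the models, the parameters that matter,
the numerical conventions, and what the synthetic test beds do and do not
establish.

## Coordinates and gene models

All genomic coordinates are 0-based half-open; GTF input is converted on
read, BED is taken as-is. A position exactly on a region boundary belongs
to the downstream region in transcript orientation. Each gene is reduced
to a single representative model — the transcript whose 3ʹ end is
3ʹ-most — because every statistic here operates at gene level; isoform
structure inside the transcript body is irrelevant except for the last
exon, the stop codon, and intron boundaries. For a gene with at least two
last-exon 3ʹUTR PASs, the 3ʹUTR splits at the proximal site into the
constitutive UTR (cUTR: stop codon → proximal PAS, present in all
isoforms) and the alternative UTR (aUTR: proximal → distal PAS, present
only in long isoforms). When more than two annotated sites exist, the
first and last define the regions (the RNA-seq scheme); the
3ʹ-end-sequencing scheme instead selects the two most abundant sites per
gene by observed reads. PASs are assigned strand-matched only; a site
inside more than one same-strand gene is left unassigned and logged.

## PAS reads and clustering

A 3ʹ-end read that truly spans the poly(A) junction retains part of the
tail as non-genomic T residues after alignment. Two filters define a PAS
read: mapping quality ≥ 10 (`min_mapq`) and ≥ 2 non-genomic Ts
(`min_T`); the second removes internal-priming artifacts, which carry 0–1
incidental Ts. Cleavage is microheterogeneous over tens of nucleotides,
so positions within 24 nt are clustered. The exact clustering algorithm
is a design choice: single linkage with a 24-nt rule can chain
indefinitely, so we use greedy seeding by abundance — positions are
visited in decreasing pooled read count (ties to the 5ʹ-most in
transcript orientation); a position joins its nearest existing seed
within 24 nt (distance ties to the 5ʹ-most seed) or becomes a new seed.
This bounds every member's distance to its representative by the window
and makes output independent of input order. Clustering runs on events
pooled across samples, so cluster identities are shared between
conditions by construction.

Two normalizations coexist because they answer different questions:
within-sample RPM (reads per million PAS reads) for isoform-level
abundances, and median-of-ratios size factors (the classical
count-matrix normalization: each sample's factor is the median over
all-nonzero genes of the ratio of its count to the gene's geometric
mean) for cross-sample gene-level expression. Size factors are anchored
to the geometric-mean pseudo-reference, so only factor ratios — and the
normalized counts — are meaningful, not the factors' absolute scale.

## RED: the APA statistic

The Relative Expression Difference is the between-sample difference of a
within-gene log2 isoform ratio:

* 3ʹ-end data: `RED = Δ log2((dPAS + 0.5)/(pPAS + 0.5))` over the two
  most abundant last-exon isoforms (distal over proximal, so negative
  RED = 3ʹUTR shortening);
* RNA-seq: `RED = Δ log2((aUTR + 0.5)/(cUTR + 0.5))` over region read
  counts. Under uniform coverage, cUTR reads ∝ expression × cUTR length
  and aUTR reads ∝ expression × ψ × aUTR length (ψ = long-isoform
  fraction), so expression and both length terms cancel between samples
  and the RED estimates Δ log2 ψ.

Because the ratio is within-gene and within-sample, sequencing depth
cancels and the RED needs no normalization. The 0.5 pseudocount appears
inside every log2 of counts and never inside an exact-test table, which
always sees raw counts. A gene enters an APA comparison only if each
compared isoform/region has ≥ 5 reads summed over the two samples
(`min_reads`) — the annotation databases give no usable eligibility rule
at this granularity, so this guard is our documented substitute, chosen
to keep the pseudocount's bias ≪ the sampling noise.

Significance: unreplicated designs use the two-sided Fisher's exact test
on the 2×2 raw-count table; replicated designs use a Welch t-test on
per-replicate log2 ratios. The latter deliberately replaces
negative-binomial isoform-ratio models (DEXSeq-style): at pseudo-bulk
and simulation depths the per-replicate log-ratio is approximately
normal and the Welch test is assumption-light, dependency-free and easy
to audit; it will be anticonservative when biological overdispersion is
large and replicates are few. Two calling dialects are implemented,
selectable via `sig_rule`: `abundance5` (default) calls a gene when
p < 0.05 and the long-isoform (distal) fraction changes by more than 5
percentage points; `ratio20` when p < 0.05 and the isoform expression
ratio changes by more than 20% (|RED| > log2 1.2). Note the two are not
nested: a 5-point fraction change near ψ = 0.5 moves the odds by ~22%,
while a large odds change at extreme ψ can move the fraction by < 5
points.

For unreplicated RNA-seq REDs an uncertainty is attached by resampling
each sample's (cUTR, aUTR) counts multinomially 20 times and taking the
SD of the recomputed REDs; with replicates the SD comes from the
replicate scatter. Intronic polyadenylation (IPA) uses the identical
machinery with summed intronic PAS reads as numerator against summed
last-exon (TPA) reads: a significant increase of the IPA fraction is
"activated". Multiple testing: raw p-values drive the per-gene calls for
APA (mirroring the per-gene exact-test convention); Benjamini–Hochberg
FDR is applied where a tally over a gene cohort is reported
(differential expression, stability contrasts).

## aUTR-length binning

Genes are sorted by aUTR length and cut into `n_bins` (default 5)
near-equal groups; runs of tied lengths stay together in the lower bin
so bin boundaries never split a length value. Each bin reports the
median of the metric and a bootstrap SEM of the median (100 resamples,
seeded) — the SEM of a median has no clean closed form, and the
plotting convention this mirrors is "median ± SEM". Between-bin
significance is a two-sided Wilcoxon rank-sum on the first vs last bin.

## Differential expression (minimal caller)

Gene-level expression uses coding-region read counts only, keeping the
reads that measure expression disjoint from the 3ʹUTR reads that measure
APA. Counts are size-factor normalized; unreplicated designs get a
Fisher test of the gene against the rest of its library, replicated
designs a Welch t-test on log2 normalized counts; calls require
fold change > 1.2 and BH FDR < 0.05 by default. This caller exists to
feed gene-set construction (common-upregulated intersections), not to
compete with full NB-GLM packages.

## Single-cell APA (scSAAP)

Per-cell read counts are too sparse for per-cell APA statistics, so the
unit of analysis is the pseudo-bulk group: cluster labels are an input
(any standard graph-clustering tool; a seeded k-means on marker-score
vectors is the built-in fallback), clusters are assigned to cell
subtypes by a marker panel, and all reads of a group are summed before
the bulk RED machinery runs unchanged. Marker panels follow a strict
consensus rule: a gene qualifies only if ≥ 2 independent studies assign
it the same subtype and none assigns a different one. Cells are CP10K +
log1p normalized (so assignment is invariant to per-cell depth); a
cluster's subtype is the argmax of its mean per-subtype marker score,
left unassigned when the top two scores tie within `margin` (default 0).

Within a subtype, cells are ranked by their own-subtype marker score and
split into equal "near"/"far" halves (odd counts: extra cell to near;
ties broken by cell id). The ranking is an explicit, deterministic
surrogate for trajectory distance from the lineage origin — more
differentiated cells express their subtype's markers more highly — and
makes no claim of equivalence to an embedding-based pseudotime geometry.

Each group's per-gene RED is taken against the pool of all assigned
cells as common reference, so group REDs share one baseline; per-group
median REDs are then centered on their mean (or median) across groups.
Aggregation is an exact integer sum, so pseudo-bulk APA on a pooled
partition is bit-identical to bulk APA on the pooled counts.

A caveat that matters for interpretation: with 3ʹ-biased single-cell
protocols, reads sit at isoform 3ʹ ends, so aUTR reads count long
isoforms and cUTR reads count short isoforms. The aUTR/cUTR RED then
estimates the change in log2 isoform *odds*, Δ log2(ψ/(1−ψ)), rather
than Δ log2 ψ as under full-length coverage. Both are zero together and
share sign; magnitudes differ.

## Stability Scores

A short metabolic-labeling pulse (default 1 h) marks newly made RNA.
Under first-order decay, steady-state abundance ∝ k_syn·t½/ln 2 and the
labeled fraction after a pulse of length t is 1 − exp(−t·ln 2/t½), so

    Stability Score = log2(steady-state RPM / labeled RPM)
                    = −log2(1 − exp(−t·ln 2 / t½)) + constant.

Each fraction is RPM-normalized separately (the two libraries are
sequenced independently) and the pseudocount is applied to raw counts
before normalization. Labeling and recovery efficiencies shift all
scores by a shared constant, so scores are comparable within an
experiment and exactly so between isoforms of one gene, where the
constant cancels; an optional median-centering flag removes it for
display. The per-gene contrast is score(long) − score(short), with
Fisher's exact test on the raw (short, long) × (total, labeled) table
and BH FDR across genes; the same contrast serves IPA vs TPA isoforms.
No synthesis or decay rates are estimated — the score is a monotone
readout of half-life, not a kinetic fit.

## Motif and gene-set statistics

Tetramer enrichment between two sequence sets counts, for each of the
256 DNA 4-mers, the sequences containing it at least once (a clean 2×2;
an occurrence-count mode normalizing per sliding window is available
behind a flag since "frequency" is ambiguous), tests the 2×2 with
Fisher's exact test, and reports signed −log10 p, positive when enriched
in set A — antisymmetric under swapping the sets and zero at p = 1.
Counting is in the DNA alphabet; a display helper renders U-rich motifs.

GO enrichment is the upper-tail hypergeometric test, deliberately
without multiple-testing adjustment (the output is a ranked shortlist,
not a family of calls). Two filters shape the report: terms annotating
more than 1000 universe genes are discarded as uninformatively generic,
and, walking terms from most to least significant (ties: larger overlap,
then term id, for determinism), any term sharing more than 75% of its
genes with an already-kept term is discarded as redundant. The
term→gene table is an input; no ontology is bundled and no DAG
propagation is performed.

The secretion-program gene set (USPS-style) is constructed by
intersecting the upregulated genes of two independent differentiation
models (same DE thresholds), running the filtered GO enrichment on the
intersection, and keeping the intersection genes annotated to the top
three kept terms. Distribution-shift questions ("is this statistic
shifted in the set?") use the two-sided Kolmogorov–Smirnov and Wilcoxon
rank-sum tests against the remaining genes (or the full distribution,
configurable). Sample-level coupling of APA to a gene program is a
Pearson correlation between per-sample median REDs and per-sample mean
set expression (≥ 3 samples); an exploratory per-gene mode correlates
each gene's RED profile with the program and flags the bottom 5% most
negative correlations.

## The synthetic-data generator

Every pipeline input can be generated with known ground truth, making
all recovery claims testable without external data. The toy genome
places two-exon genes (CDS 600–1500 nt, 1 kb intron, cUTR 150–800 nt
log-uniform, aUTR 100–3000 nt log-uniform) on alternating strands; 30%
of genes carry an intronic PAS mid-intron. Per-gene long-isoform
fractions ψ start uniform in (0.3, 0.7) in the reference; the test
condition shifts each gene's log2 isoform odds by a programmed true RED
(default Normal(−0.15, 0.4), matching a globally shortening
differentiation; alternative layouts plant a 10:1
shortening/lengthening mixture at fixed magnitude or effects
proportional to aUTR length).

3ʹ-end reads: per gene and sample, 1000 reads choose intronic (per the
gene's IPA fraction) or distal-vs-proximal (Bernoulli ψ); the cleavage
position adds integer Gaussian noise (SD 5 nt) hard-truncated at ±12 nt
— the truncation guarantees one cluster per planted site under the
24-nt rule, so cluster-recovery tests are exact rather than
probabilistic. Genuine reads draw 2–6 non-genomic Ts and MAPQ 30 (5%
low-MAPQ); internal-priming noise reads (rate 0.05 per true read) land
uniformly in the gene with 0–1 Ts, so the T filter removes exactly this
class. RNA-seq region counts are Poisson with the full-coverage
expectations above (≈ 2000 cUTR+aUTR reads/gene/sample), with
log-normal expression jitter across replicates (SD 0.25). Single cells:
three subtypes (VCT, SCT, EVT; 200 cells each, 500 UMIs) with 23
markers per subtype amplified 8-fold scaled by a per-cell
differentiation coordinate u ~ U(0, 1); programmed ψ per subtype (VCT
0.50, SCT 0.25, EVT 0.40 — the secretory subtype expresses the shortest
3ʹUTRs) tilted by −0.1·(u−0.5) along the gradient; per-cell region
counts follow the 3ʹ-tag model (aUTR ~ Binomial(reads, ψ)). Labeling:
short-isoform half-lives log-uniform in 0.25–16 h; the long isoform's
log2 half-life is reduced by 0.67 per kb of aUTR, encoding
length-proportional destabilizing content; an expectation mode emits
noise-free means for closed-form checks. Region sequences can be
generated with TTTT planted at ~3 copies/kb of aUTR to mirror that
coupling at the motif level.

Every generator is a pure function of (config, seed) via named RNG
streams, so outputs are byte-identical across runs; the pipeline
serializes reports with fixed float formatting and sorted keys for the
same reason (timestamps go only to the log).

What the generator does **not** emulate — and hence what passing tests
do not show about real data: no mappability or GC structure, no
internal-priming sequence context (noise is positionally uniform), no
overlapping or antisense genes, no ambient RNA, doublets or batch
effects in cells, no overdispersion beyond Poisson/multinomial noise,
and no uncertainty in the annotation itself. Recovery results bound the
estimator's statistical behaviour, not the upstream alignment and
annotation error of a real experiment.

## Problem sizes and numerical notes

The shipped property checks run at desk scale: 500 genes × 1000
reads/gene for RED recovery, 1000 genes for the null, 2500 genes (≈ 500
per bin) for length-binned trends, 600 cells for scSAAP, exhaustive 2×2
tables with margins ≤ 30 for the exact-test cross-check. At 1000
reads/gene/sample the sampling SD of a single-gene RED is ≥ 0.13 (two
binomial log-odds), so single-gene REDs at this depth carry ±0.25-ish
95% intervals while cohort medians are precise to ~0.01 — the package's
claims are calibrated accordingly, and per-gene intervals should be read
from the bootstrap/replicate SDs it reports. Degenerate inputs are
defined, not fatal: a 2×2 with a zero margin gives p = 1; identical
constant samples give rank-test p = 1; zero-variance vectors give NaN
correlations; an empty pseudo-bulk group or an unsatisfiable size-factor
reference raises with advice.
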