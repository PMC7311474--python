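"""3'-end sequencing reads -> clustered, normalized poly(A)-site counts.

The 3'READS-style protocol sequences the 3' end of poly(A)+ transcripts;
after alignment a genuine poly(A) junction read retains a stretch of
non-genomic T residues (the reverse-complemented tail) as a soft clip.
This module filters alignments to PAS reads (MAPQ >= 10 and >= 2
non-genomic Ts by default, the second condition removing internal-priming
artifacts), clusters nearby cleavage positions (cleavage is heterogeneous
over tens of nucleotides around a site), and computes cross-sample size
factors by the median-of-ratios method.

Clustering is greedy by abundance: positions are visited in decreasing
pooled read count (ties to the 5'-most position in transcript
orientation); a position within the window (24 nt) of an existing seed
joins its nearest seed, otherwise it becomes a new seed. Unlike
single-linkage this bounds every member's distance to its representative
by the window and is order-independent.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLUSTER_WINDOW = 24  # nt; maximum distance between clustered sites
MIN_MAPQ = 10
MIN_NONGENOMIC_T = 2


@dataclass(frozen=True)
class AlignedRead3p:
    """One aligned 3'-end read reduced to the fields the caller needs.

    ``cleavage_position`` is the genomic coordinate of the alignment end
    corresponding to the transcript 3' end (last transcribed nucleotide);
    ``nongenomic_T`` counts soft-clipped T residues abutting the poly(A)
    tail, computed upstream from the CIGAR/sequence or by the simulator.
    """

    chrom: str
    strand: str
    cleavage_position: int
    mapq: int
    nongenomic_T: int
    sample: str = "s1"

    def __post_init__(self) -> None:
        if self.mapq < 0 or self.nongenomic_T < 0:
            raise ValueError("mapq and nongenomic_T must be >= 0")


@dataclass(frozen=True)
class PasCluster:
    """A clustered cleavage site.

    ``representative`` is the member position with the largest pooled
    count (ties: 5'-most in transcript orientation); every member lies
    within the clustering window of it. ``counts`` maps sample -> summed
    read count.
    """

    chrom: str
    strand: str
    representative: int
    members: tuple[int, ...]
    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.representative}"


@dataclass
class FilterStats:
    kept: int = 0
    discarded_mapq: int = 0
    discarded_T: int = 0


# ---------------------------------------------------------------------------
# input


def read_alignments_tsv(path: str | Path) -> list[AlignedRead3p]:
    """Read the documented TSV (chrom, position, strand, mapq, nongenomic_T, sample)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "position", "strand", "mapq", "nongenomic_T", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        AlignedRead3p(r.chrom, r.strand, int(r.position), int(r.mapq),
                      int(r.nongenomic_T), str(r.sample))
        for r in df.itertuples(index=False)
    ]


def read_alignments_sam(path: str | Path, sample: str | None = None) -> list[AlignedRead3p]:
    """Extract 3'-end reads from a SAM/BAM file.

    The read's 5' end carries the (reverse-complemented) tail, so a read
    whose transcript is on '+' maps to the reverse genome strand: its
    non-genomic Ts appear as trailing soft-clipped 'A's in reference
    orientation and the cleavage position is the alignment's reference
    end. The mirror case holds for '-' transcripts.
    """
    import pysam

    sample = sample or Path(path).stem
    reads: list[AlignedRead3p] = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            seq = aln.query_sequence or ""
            cig = aln.cigartuples
            if aln.is_reverse:  # transcript on '+'
                strand = "+"
                cleavage = aln.reference_end - 1
                n_clip = cig[-1][1] if cig[-1][0] == 4 else 0
                clipped = seq[len(seq) - n_clip:] if n_clip else ""
                n_t = _leading(clipped, "A")
            else:  # transcript on '-'
                strand = "-"
                cleavage = aln.reference_start
                n_clip = cig[0][1] if cig[0][0] == 4 else 0
                clipped = seq[:n_clip][::-1] if n_clip else ""
                n_t = _leading(clipped, "T")
            reads.append(
                AlignedRead3p(aln.reference_name, strand, cleavage,
                              aln.mapping_quality, n_t, sample)
            )
    return reads


def _leading(s: str, base: str) -> int:
    n = 0
    for c in s:
        if c.upper() != base:
            break
        n += 1
    return n


# ---------------------------------------------------------------------------
# PAS-read calling


def call_pas_reads(
    reads: Iterable[AlignedRead3p] | pd.DataFrame,
    min_mapq: int = MIN_MAPQ,
    min_T: int = MIN_NONGENOMIC_T,
):
    """Keep reads with mapq >= min_mapq and nongenomic_T >= min_T.

    Accepts a sequence of :class:`AlignedRead3p` (returned as a filtered
    list) or an alignment DataFrame with columns chrom, position, strand,
    mapq, nongenomic_T, sample (returned as a filtered DataFrame). Also
    returns the per-reason discard tally; reads failing both filters are
    counted under mapq (filters applied in that order).
    """
    if isinstance(reads, pd.DataFrame):
        bad_mapq = reads["mapq"] < min_mapq
        bad_t = ~bad_mapq & (reads["nongenomic_T"] < min_T)
        kept_df = reads[~bad_mapq & ~bad_t]
        stats = FilterStats(len(kept_df), int(bad_mapq.sum()), int(bad_t.sum()))
        if kept_df.empty:
            logger.warning("call_pas_reads: no reads passed the PAS-read filters")
        return kept_df, stats
    stats = FilterStats()
    kept: list[AlignedRead3p] = []
    for r in reads:
        if r.mapq < min_mapq:
            stats.discarded_mapq += 1
        elif r.nongenomic_T < min_T:
            stats.discarded_T += 1
        else:
            stats.kept += 1
            kept.append(r)
    if not kept:
        logger.warning("call_pas_reads: no reads passed the PAS-read filters")
    return kept, stats


# ---------------------------------------------------------------------------
# clustering


def cluster_pas(
    reads: Iterable[AlignedRead3p] | pd.DataFrame,
    window: int = CLUSTER_WINDOW,
) -> list[PasCluster]:
    """Cluster cleavage positions within ``window`` nt, per chrom+strand.

    Greedy seeding by decreasing pooled count (tie: 5'-most position in
    transcript orientation); each remaining position joins its nearest
    seed within the window (distance tie: 5'-most seed). Output is sorted
    by (chrom, strand, representative) and independent of input record
    order. ``reads`` may be :class:`AlignedRead3p` records or an
    alignment DataFrame (chrom, position, strand, sample).
    """
    import bisect

    pooled: dict[tuple[str, str], dict[int, int]] = defaultdict(lambda: defaultdict(int))
    per_sample: dict[tuple[str, str], dict[int, dict[str, int]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(int))
    )
    if isinstance(reads, pd.DataFrame):
        grouped = reads.groupby(["chrom", "strand", "position", "sample"],
                                sort=False).size()
        for (chrom, strand, pos, sample), n in grouped.items():
            key = (chrom, strand)
            pooled[key][int(pos)] += int(n)
            per_sample[key][int(pos)][str(sample)] += int(n)
    else:
        for r in reads:
            key = (r.chrom, r.strand)
            pooled[key][r.cleavage_position] += 1
            per_sample[key][r.cleavage_position][r.sample] += 1

    clusters: list[PasCluster] = []
    for key in sorted(pooled):
        chrom, strand = key
        counts = pooled[key]
        # 5'-most in transcript orientation: small coord on '+', large on '-'
        orient = (lambda p: p) if strand == "+" else (lambda p: -p)
        order = sorted(counts, key=lambda p: (-counts[p], orient(p)))
        seeds_sorted: list[int] = []  # by position, for nearest lookup
        assign: dict[int, list[int]] = {}
        for pos in order:
            i = bisect.bisect_left(seeds_sorted, pos)
            best = None
            for s in seeds_sorted[max(0, i - 1):i + 1]:
                d = abs(pos - s)
                if d <= window:
                    cand = (d, orient(s))
                    if best is None or cand < best[0]:
                        best = (cand, s)
            if best is None:
                bisect.insort(seeds_sorted, pos)
                assign[pos] = [pos]
            else:
                assign[best[1]].append(pos)
        for seed in seeds_sorted:
            members = tuple(sorted(assign[seed]))
            ctr: dict[str, int] = defaultdict(int)
            for m in members:
                for smp, n in per_sample[key][m].items():
                    ctr[smp] += n
            clusters.append(
                PasCluster(chrom, strand, seed, members, dict(sorted(ctr.items())))
            )
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.representative))
    return clusters


def clusters_to_frame(clusters: Sequence[PasCluster],
                      samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate clusters: one row per cluster, one count column per sample."""
    if samples is None:
        samples = sorted({s for c in clusters for s in c.counts})
    rows = []
    for c in clusters:
        row = {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "strand": c.strand,
            "representative": c.representative,
            "span": (c.members[-1] - c.members[0]) if c.members else 0,
        }
        for s in samples:
            row[s] = int(c.counts.get(s, 0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster_id") if rows else pd.DataFrame(
        columns=["chrom", "strand", "representative", "span", *samples]
    )


def write_clusters(clusters: Sequence[PasCluster], bed_path: str | Path,
                   counts_path: str | Path) -> None:
    """Write clusters as BED6 plus a cluster x sample counts TSV."""
    with open(bed_path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.representative}\t{c.representative + 1}\t"
                f"{c.cluster_id}\t{c.total}\t{c.strand}\n"
            )
    clusters_to_frame(clusters).to_csv(counts_path, sep="\t")


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count matrix).

    For each gene with nonzero counts in every sample, the ratio of each
    sample's count to the gene's geometric mean is taken; a sample's
    factor is the median of these ratios. Raises if no gene is nonzero
    everywhere (filter first, or aggregate to pseudo-bulk).
    """
    if counts.ndim != 2 or counts.shape[1] == 0:
        raise ValueError("counts must be a genes x samples matrix")
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ValueError(
            "no gene has nonzero counts in all samples; filter low-count "
            "genes or aggregate sparse samples to pseudo-bulk first"
        )
    log = np.log(pos.astype(float))
    log_geo = log.mean(axis=1)
    factors = np.exp(log.sub(log_geo, axis=0).median(axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def rpm(counts: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Reads-per-million within each sample (column)."""
    if isinstance(counts, pd.Series):
        return counts * 1e6 / counts.sum()
    return counts * 1e6 / counts.sum(axis=0)
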