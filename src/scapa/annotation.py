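"""Gene models, poly(A)-site annotation, and cUTR/aUTR region derivation.

A gene is represented by a single :class:`GeneModel` (the transcript with
the 3'-most annotated end when several exist). Poly(A) sites (PASs) from a
database or from 3'-end-read clustering are classified against the model:
sites in the 3'UTR of the last exon drive 3'UTR APA analysis, sites in
introns drive IPA analysis. For genes with at least two 3'UTR PASs the
3'UTR is split at the proximal site into the constitutive UTR (cUTR,
stop codon to proximal PAS, present in every isoform) and the alternative
UTR (aUTR, proximal to distal PAS, present only in long isoforms).

All coordinates are 0-based half-open on the genome. A position exactly at
a region boundary belongs to the downstream region (in transcript
orientation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

UTR3 = "utr3_last_exon"
INTRONIC = "intronic"
OTHER = "other"


class AnnotationParseError(ValueError):
    """Malformed annotation input; message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: exon structure, CDS, and derived last-exon 3'UTR.

    ``exons`` are genomic intervals sorted by start; ``cds`` is the subset
    of exonic sequence that codes (empty for non-coding genes, which are
    retained but flagged).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def last_exon(self) -> Interval:
        """3'-most exon in transcript orientation."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    @property
    def stop_codon_end(self) -> int:
        """Transcript-orientation end of the CDS as a genomic coordinate.

        On '+' this is the half-open CDS end; on '-' the CDS start, so in
        both cases the last-exon 3'UTR is the half-open interval between
        ``stop_codon_end`` and the outer edge of the last exon.
        """
        if not self.coding:
            raise ValueError(f"{self.gene_id} is non-coding: no stop codon")
        return self.cds[-1][1] if self.strand == "+" else self.cds[0][0]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )

    def utr3_interval(self) -> Interval | None:
        """Last-exon 3'UTR as a genomic interval, or None if empty."""
        if not self.coding:
            return None
        le = self.last_exon
        stop = self.stop_codon_end
        iv = (stop, le[1]) if self.strand == "+" else (le[0], stop)
        return iv if iv[1] > iv[0] else None

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class PasAnnotation:
    """A poly(A) site placed on a gene model.

    ``rank`` orders a gene's last-exon 3'UTR sites 5'->3' in transcript
    orientation (1 = most proximal); it is None for other classes.
    """

    gene_id: str | None
    chrom: str
    strand: str
    position: int
    location_class: str
    rank: int | None = None


@dataclass(frozen=True)
class RegionSet:
    """cUTR/aUTR/CDS intervals for one gene with >=2 3'UTR PASs."""

    gene_id: str
    chrom: str
    strand: str
    cutr: Interval
    autr: Interval
    cds: tuple[Interval, ...]

    @property
    def autr_length(self) -> int:
        return self.autr[1] - self.autr[0]

    @property
    def cutr_length(self) -> int:
        return self.cutr[1] - self.cutr[0]


# ---------------------------------------------------------------------------
# readers


def load_gene_models(path: str | Path, fmt: str | None = None) -> dict[str, GeneModel]:
    """Load one GeneModel per gene from a BED12 or GTF file.

    When a gene has several transcripts the one with the 3'-most end (in
    transcript orientation) is used. Returns a dict keyed and ordered by
    gene_id. Non-coding entries are retained (``coding`` is False).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gtf" if suffix in (".gtf", ".gff", ".gff3") else "bed"
    if fmt == "bed":
        transcripts = _read_bed12(path)
    elif fmt == "gtf":
        transcripts = _read_gtf(path)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    models: dict[str, GeneModel] = {}
    for gene_id in sorted(transcripts):
        best = max(transcripts[gene_id], key=_three_prime_key)
        models[gene_id] = best
        if not best.coding:
            logger.info("gene %s has no CDS; flagged non-coding", gene_id)
    return models


def _three_prime_key(m: GeneModel):
    # 3'-most end in transcript orientation; tie-break on span for stability
    return (m.end, m.end - m.start) if m.strand == "+" else (-m.start, m.end - m.start)


def _read_bed12(path: Path) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED12 needs 12 fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start = int(fields[6])
                thick_end = int(fields[7])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationParseError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            exons = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            cds = _intersect_intervals(exons, thick_start, thick_end)
            try:
                model = GeneModel(name, chrom, strand, exons, cds)
            except ValueError as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
            out.setdefault(name, []).append(model)
    return out


def _read_gtf(path: Path) -> dict[str, list[GeneModel]]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[tuple[str, str], list] = {}
    cds: dict[tuple[str, str], list[Interval]] = {}
    meta: dict[tuple[str, str], tuple[str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes.get("transcript_id", [gene_id])[0]
        except KeyError as exc:
            raise AnnotationParseError(
                f"{path}: feature at {feat.seqid}:{feat.start} missing {exc}"
            ) from None
        key = (gene_id, tx_id)
        meta[key] = (feat.seqid, feat.strand)
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        (exons if feat.featuretype == "exon" else cds).setdefault(key, []).append(iv)

    out: dict[str, list[GeneModel]] = {}
    for key, (chrom, strand) in meta.items():
        gene_id, _ = key
        ex = tuple(sorted(exons.get(key, cds.get(key, []))))
        cd = tuple(sorted(cds.get(key, [])))
        out.setdefault(gene_id, []).append(GeneModel(gene_id, chrom, strand, ex, cd))
    return out


def _intersect_intervals(exons: Sequence[Interval], lo: int, hi: int) -> tuple[Interval, ...]:
    if hi <= lo:
        return ()
    return tuple(
        (max(s, lo), min(e, hi)) for s, e in exons if min(e, hi) > max(s, lo)
    )


def read_pas_bed(path: str | Path) -> pd.DataFrame:
    """Read a PAS database as BED6 (name = gene_id, start = cleavage site).

    Returns a DataFrame with columns chrom, position, strand, gene_id.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    f"{path}:{lineno}: BED6 needs 6 fields, got {len(fields)}"
                )
            rows.append(
                {
                    "chrom": fields[0],
                    "position": int(fields[1]),
                    "strand": fields[5],
                    "gene_id": fields[3],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "position", "strand", "gene_id"])


# ---------------------------------------------------------------------------
# classification and regions


def classify_pas(
    models: Mapping[str, GeneModel],
    pas: pd.DataFrame | Iterable,
) -> list[PasAnnotation]:
    """Assign each PAS to at most one gene and a location class.

    ``pas`` is a DataFrame with columns chrom, position, strand and
    optionally gene_id (a hint that restricts the search to that gene), or
    an iterable of (chrom, position, strand[, gene_id]) tuples. Sites that
    match no gene — or that fall, strand-matched, inside more than one
    gene — are returned with gene_id None and class "other"; their count
    is logged. Last-exon 3'UTR sites of each gene get ranks 1..n ordered
    5'->3' in transcript orientation.
    """
    if not isinstance(pas, pd.DataFrame):
        pas = _tuples_to_frame(pas)
    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for m in models.values():
        by_loc.setdefault((m.chrom, m.strand), []).append(m)
    for key in by_loc:
        by_loc[key].sort(key=lambda m: m.start)

    annotated: list[PasAnnotation] = []
    n_unassigned = 0
    n_ambiguous = 0
    has_hint = "gene_id" in pas.columns
    for row in pas.itertuples(index=False):
        chrom, position, strand = row.chrom, int(row.position), row.strand
        hint = getattr(row, "gene_id", None) if has_hint else None
        gene = None
        if hint is not None and not (isinstance(hint, float) and pd.isna(hint)) and hint in models:
            cand = models[hint]
            if cand.chrom == chrom and cand.strand == strand and cand.contains(position):
                gene = cand
        if gene is None:
            hits = [
                m for m in by_loc.get((chrom, strand), []) if m.contains(position)
            ]
            if len(hits) == 1:
                gene = hits[0]
            elif len(hits) > 1:
                n_ambiguous += 1
        if gene is None:
            n_unassigned += 1
            annotated.append(PasAnnotation(None, chrom, strand, position, OTHER))
            continue
        annotated.append(
            PasAnnotation(gene.gene_id, chrom, strand, position, _locate(gene, position))
        )
    if n_unassigned:
        logger.info(
            "classify_pas: %d sites matched no gene (%d ambiguous overlaps)",
            n_unassigned,
            n_ambiguous,
        )
    return _rank_utr3(annotated)


def _tuples_to_frame(rows: Iterable) -> pd.DataFrame:
    rows = list(rows)
    width = max((len(r) for r in rows), default=3)
    cols = ["chrom", "position", "strand", "gene_id"][:width]
    return pd.DataFrame(rows, columns=cols)


def _locate(gene: GeneModel, position: int) -> str:
    utr3 = gene.utr3_interval()
    if utr3 is not None and utr3[0] <= position < utr3[1]:
        return UTR3
    for s, e in gene.introns:
        if s <= position < e:
            return INTRONIC
    return OTHER


def _rank_utr3(annotated: list[PasAnnotation]) -> list[PasAnnotation]:
    by_gene: dict[str, list[int]] = {}
    for i, a in enumerate(annotated):
        if a.gene_id is not None and a.location_class == UTR3:
            by_gene.setdefault(a.gene_id, []).append(i)
    out = list(annotated)
    for gene_id, idxs in by_gene.items():
        strand = annotated[idxs[0]].strand
        ordered = sorted(idxs, key=lambda i: annotated[i].position,
                         reverse=(strand == "-"))
        for rank, i in enumerate(ordered, start=1):
            a = annotated[i]
            out[i] = PasAnnotation(a.gene_id, a.chrom, a.strand, a.position,
                                   a.location_class, rank)
    return out


def derive_regions(
    models: Mapping[str, GeneModel],
    annotations: Iterable[PasAnnotation],
) -> dict[str, RegionSet]:
    """cUTR/aUTR regions from the first (proximal) and last (distal) 3'UTR PAS.

    Genes with fewer than two last-exon 3'UTR PASs are skipped (they carry
    no 3'UTR APA information). A proximal PAS at or upstream of the stop
    codon is a mis-configuration: the gene is excluded and logged.
    """
    utr3_by_gene: dict[str, list[PasAnnotation]] = {}
    for a in annotations:
        if a.gene_id is not None and a.location_class == UTR3:
            utr3_by_gene.setdefault(a.gene_id, []).append(a)

    regions: dict[str, RegionSet] = {}
    for gene_id in sorted(utr3_by_gene):
        sites = sorted(utr3_by_gene[gene_id], key=lambda a: a.rank)
        if len(sites) < 2:
            continue
        gene = models[gene_id]
        stop = gene.stop_codon_end
        proximal = sites[0].position
        distal = sites[-1].position
        if gene.strand == "+":
            ok = stop < proximal < distal
            cutr, autr = (stop, proximal), (proximal, distal)
        else:
            ok = distal < proximal < stop
            cutr, autr = (proximal, stop), (distal, proximal)
        if not ok:
            logger.warning(
                "derive_regions: %s proximal PAS not strictly between stop codon "
                "and distal PAS; gene excluded", gene_id,
            )
            continue
        regions[gene_id] = RegionSet(gene_id, gene.chrom, gene.strand, cutr, autr,
                                     gene.cds)
    return regions


def write_regions_bed(regions: Mapping[str, RegionSet], path: str | Path) -> None:
    """Write cUTR/aUTR regions as BED6; the name field is gene_id|region."""
    with open(path, "w") as fh:
        for gene_id in sorted(regions):
            r = regions[gene_id]
            for label, (s, e) in (("cUTR", r.cutr), ("aUTR", r.autr)):
                fh.write(
                    f"{r.chrom}\t{s}\t{e}\t{gene_id}|{label}\t0\t{r.strand}\n"
                )
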