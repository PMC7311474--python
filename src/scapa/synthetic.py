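"""Synthetic data with known ground truth for every pipeline stage.

The generator builds a toy genome of two-exon genes (two 3'UTR PASs per
gene, an intronic PAS in a configurable fraction) and simulates, from
explicit per-gene parameters:

* 3'-end-sequencing alignments: per molecule the isoform is drawn from
  the gene's long-isoform fraction psi (or the intronic fraction for IPA
  genes), the cleavage position is the PAS plus truncated-Gaussian
  heterogeneity (SD 5 nt, hard-capped at +/-12 nt so that the 24-nt
  clustering rule recovers exactly one cluster per site), and genuine
  poly(A) reads carry 2-6 non-genomic Ts while internal-priming noise
  reads carry 0-1;
* bulk RNA-seq region counts under full-length coverage: cUTR reads
  scale with expression x cUTR length, aUTR reads with expression x psi
  x aUTR length (only long isoforms cover the aUTR), CDS reads with
  expression x CDS length; Poisson sampling, log-normal replicate jitter;
* single cells with planted subtype structure: marker genes elevated in
  their subtype with a within-subtype differentiation gradient u in
  [0, 1] that also tilts psi; per-cell region counts follow a 3'-tag
  model (aUTR reads ~ psi, cUTR reads ~ 1-psi);
* paired total/labeled (4sU-pulse) counts under first-order decay, so
  the true Stability Score is the closed form
  -log2(1 - exp(-t*ln2/t_half)) plus a global constant.

Every generator is a pure function of (config, seed): given the same
SimConfig the emitted records and files are byte-identical across runs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel

READ_COLUMNS = ["chrom", "position", "strand", "mapq", "nongenomic_T", "sample"]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Lengths are in nucleotides, half-lives and the labeling time in
    hours. Fractions are in [0, 1].
    """

    seed: int

    # genome geometry
    n_genes: int = 200
    utr5_len: int = 100
    cds_len_range: tuple[int, int] = (600, 1500)
    intron_len: int = 1000
    cutr_len_range: tuple[int, int] = (150, 800)       # log-uniform
    autr_len_range: tuple[int, int] = (100, 3000)      # log-uniform
    utr3_tail: int = 50              # last exon extends past the distal PAS
    intergenic: int = 5000
    n_chroms: int = 2
    frac_ipa_genes: float = 0.3

    # 3' end sequencing
    reads_per_gene: int = 1000
    cleavage_sd: float = 5.0
    cleavage_max: int = 12
    noise_rate: float = 0.05         # internal-priming reads per true read
    true_T_range: tuple[int, int] = (2, 6)
    noise_T_range: tuple[int, int] = (0, 1)
    mapq_good: int = 30
    frac_low_mapq: float = 0.05

    # programmed APA change (test vs ref)
    psi_ref_range: tuple[float, float] = (0.3, 0.7)
    red_mean: float = -0.15          # per-gene true RED ~ Normal(mean, sd)
    red_sd: float = 0.4
    # alternative effect layouts (override red_mean/red_sd when set):
    # (p_shortening, magnitude): true RED = -magnitude w.p. p, +magnitude else
    red_mixture: tuple[float, float] | None = None
    # RED proportional to aUTR length: true RED = -slope * aUTR_len / 1 kb
    red_length_slope: float | None = None
    ipa_frac_ref_range: tuple[float, float] = (0.05, 0.2)
    ipa_shift_mean: float = 0.5      # log2 change of IPA odds, Normal(mean, sd)
    ipa_shift_sd: float = 0.5

    # bulk RNA-seq
    region_reads_per_gene: int = 2000    # expected cUTR+aUTR reads per sample
    replicate_jitter_sd: float = 0.25    # log-normal expression jitter

    # expression
    expression_sigma: float = 0.5        # log-normal spread of gene expression
    expr_log2fc_sd: float = 0.0          # per-gene expression change (test/ref)

    # stability / metabolic labeling
    label_time: float = 1.0
    half_life_range: tuple[float, float] = (0.25, 16.0)   # log-uniform, short isoform
    stability_slope: float = 0.67    # long-isoform log2 t-half deficit per kb of aUTR
    reads_per_isoform: int = 1000

    # single cells
    subtypes: tuple[str, ...] = ("EVT", "SCT", "VCT")
    cells_per_subtype: int = 200
    umis_per_cell: int = 500
    markers_per_subtype: int = 23
    marker_effect: float = 8.0
    psi_subtype: Mapping[str, float] = field(
        default_factory=lambda: {"VCT": 0.50, "SCT": 0.25, "EVT": 0.40})
    psi_gradient: float = 0.1        # psi drop from near to far along u
    region_reads_per_cell: int = 500

    def rng(self, stream: int) -> np.random.Generator:
        """Named RNG stream: independent but fully determined by the seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class Genome:
    """Simulated annotation plus per-gene ground truth."""

    config: SimConfig
    models: dict[str, GeneModel]
    pas_db: pd.DataFrame          # chrom, position, strand, gene_id, kind
    truth: pd.DataFrame           # per-gene parameters, indexed by gene_id

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_bed12(self.models, outdir / "genes.bed")
        pas = self.pas_db
        with open(outdir / "pas.bed", "w") as fh:
            for r in pas.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t"
                         f"{r.gene_id}\t0\t{r.strand}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t")


def write_bed12(models: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            start = m.start
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, e in m.exons)
            thick = (m.cds[0][0], m.cds[-1][1]) if m.cds else (start, start)
            fh.write(
                f"{m.chrom}\t{start}\t{m.end}\t{gene_id}\t0\t{m.strand}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(m.exons)}\t{sizes},\t{starts},\n"
            )


def _log_uniform(rng, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size))


def _trunc_normal_int(rng, sd: float, max_dev: int, size: int) -> np.ndarray:
    """Rounded Normal(0, sd) rejected outside [-max_dev, +max_dev]."""
    out = np.rint(rng.normal(0.0, sd, size)).astype(np.int64)
    bad = np.abs(out) > max_dev
    while bad.any():
        out[bad] = np.rint(rng.normal(0.0, sd, int(bad.sum()))).astype(np.int64)
        bad = np.abs(out) > max_dev
    return out


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> Genome:
    """Build the toy genome, PAS database and per-gene ground truth."""
    cfg = config
    rng = cfg.rng(0)
    n = cfg.n_genes

    cds_len = rng.integers(cfg.cds_len_range[0], cfg.cds_len_range[1] + 1, n)
    cutr_len = np.rint(_log_uniform(rng, *cfg.cutr_len_range, n)).astype(int)
    autr_len = np.rint(_log_uniform(rng, *cfg.autr_len_range, n)).astype(int)
    ipa_gene = rng.random(n) < cfg.frac_ipa_genes
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    chroms = np.array([f"chr{1 + i % cfg.n_chroms}" for i in range(n)])

    psi_ref = rng.uniform(*cfg.psi_ref_range, n)
    if cfg.red_mixture is not None:
        p_short, magnitude = cfg.red_mixture
        true_red = np.where(rng.random(n) < p_short, -magnitude, magnitude)
    elif cfg.red_length_slope is not None:
        true_red = -cfg.red_length_slope * autr_len / 1000.0
    elif cfg.red_sd > 0:
        true_red = rng.normal(cfg.red_mean, cfg.red_sd, n)
    else:
        true_red = np.full(n, cfg.red_mean)
    # shift psi on the log-odds scale; psi of exactly 0/1 is a fixed point
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_test = psi_ref / (1 - psi_ref) * np.exp2(true_red)
        psi_test = np.where(psi_ref >= 1.0, 1.0,
                            np.where(psi_ref <= 0.0, 0.0,
                                     odds_test / (1 + odds_test)))

    ipa_frac_ref = rng.uniform(*cfg.ipa_frac_ref_range, n)
    ipa_shift = rng.normal(cfg.ipa_shift_mean, cfg.ipa_shift_sd, n) if cfg.ipa_shift_sd > 0 else np.full(n, cfg.ipa_shift_mean)
    ipa_odds_test = ipa_frac_ref / (1 - ipa_frac_ref) * np.exp2(ipa_shift)
    ipa_frac_test = ipa_odds_test / (1 + ipa_odds_test)

    expression = np.exp(rng.normal(0.0, cfg.expression_sigma, n))
    expr_log2fc = (rng.normal(0.0, cfg.expr_log2fc_sd, n)
                   if cfg.expr_log2fc_sd > 0 else np.zeros(n))

    t_half_short = _log_uniform(rng, *cfg.half_life_range, n)
    t_half_long = t_half_short * np.exp2(-cfg.stability_slope * autr_len / 1000.0)
    t_half_long = np.clip(t_half_long, 0.05, None)

    models: dict[str, GeneModel] = {}
    rows = []
    cursor = {f"chr{i + 1}": 10_000 for i in range(cfg.n_chroms)}
    for i in range(n):
        gene_id = f"G{i:04d}"
        chrom, strand = chroms[i], strands[i]
        cds_a = int(cds_len[i]) // 2
        cds_b = int(cds_len[i]) - cds_a
        g0 = cursor[chrom]
        if strand == "+":
            e1 = (g0, g0 + cfg.utr5_len + cds_a)
            e2s = e1[1] + cfg.intron_len
            stop = e2s + cds_b
            ppas = stop + int(cutr_len[i])
            dpas = ppas + int(autr_len[i])
            e2 = (e2s, dpas + cfg.utr3_tail)
            exons = (e1, e2)
            cds = ((g0 + cfg.utr5_len, e1[1]), (e2s, stop))
            ipa_pas = e1[1] + cfg.intron_len // 2
        else:
            dpas = g0 + cfg.utr3_tail
            ppas = dpas + int(autr_len[i])
            stop = ppas + int(cutr_len[i])
            e1 = (g0, stop + cds_b)          # last exon (3'-most in transcript)
            e2s = e1[1] + cfg.intron_len
            e2 = (e2s, e2s + cds_a + cfg.utr5_len)
            exons = (e1, e2)
            cds = ((stop, e1[1]), (e2s, e2s + cds_a))
            ipa_pas = e1[1] + cfg.intron_len // 2
        models[gene_id] = GeneModel(gene_id, chrom, strand, exons, cds)
        cursor[chrom] = exons[-1][1] + cfg.intergenic
        rows.append({
            "gene_id": gene_id, "chrom": chrom, "strand": strand,
            "stop_codon_end": stop, "ppas": ppas, "dpas": dpas,
            "ipa_pas": int(ipa_pas) if ipa_gene[i] else -1,
            "gene_start": exons[0][0], "gene_end": exons[-1][1],
            "cds_len": int(cds_len[i]), "cutr_len": int(cutr_len[i]),
            "autr_len": int(autr_len[i]),
            "expression": expression[i], "expr_log2fc": expr_log2fc[i],
            "psi_ref": psi_ref[i], "psi_test": psi_test[i],
            "true_red": true_red[i],
            "true_red_rnaseq": (np.log2(psi_test[i] / psi_ref[i])
                                if 0 < psi_ref[i] else float("nan")),
            "ipa_gene": bool(ipa_gene[i]),
            "ipa_frac_ref": ipa_frac_ref[i], "ipa_frac_test": ipa_frac_test[i],
            "true_ipa_shift": ipa_shift[i],
            "t_half_short": t_half_short[i], "t_half_long": t_half_long[i],
        })
    truth = pd.DataFrame(rows).set_index("gene_id")

    pas_rows = []
    for gene_id, t in truth.iterrows():
        for pos, kind in ((t["ppas"], "utr3"), (t["dpas"], "utr3")):
            pas_rows.append({"chrom": t["chrom"], "position": int(pos),
                             "strand": t["strand"], "gene_id": gene_id,
                             "kind": kind})
        if t["ipa_pas"] >= 0:
            pas_rows.append({"chrom": t["chrom"], "position": int(t["ipa_pas"]),
                             "strand": t["strand"], "gene_id": gene_id,
                             "kind": "intronic"})
    pas_db = pd.DataFrame(pas_rows)
    return Genome(cfg, models, pas_db, truth)


# ---------------------------------------------------------------------------
# 3' end sequencing reads


def simulate_3reads(
    genome: Genome,
    samples: Sequence[str] = ("ref", "test"),
    reads_per_gene: int | None = None,
) -> pd.DataFrame:
    """Simulate 3'-end alignments for the given samples.

    Sample names must be 'ref'/'test' (or map onto them via order): the
    first sample uses each gene's psi_ref / ipa_frac_ref, the second
    psi_test / ipa_frac_test. Returns the documented alignment TSV frame.
    """
    cfg = genome.config
    n_reads = cfg.reads_per_gene if reads_per_gene is None else reads_per_gene
    truth = genome.truth
    frames = []
    for si, sample in enumerate(samples):
        rng = cfg.rng(100 + si)
        which = "ref" if si == 0 else "test"
        for gene_id, t in truth.iterrows():
            psi = float(t[f"psi_{which}"])
            ipa_frac = float(t[f"ipa_frac_{which}"]) if t["ipa_pas"] >= 0 else 0.0
            u = rng.random(n_reads)
            is_ipa = u < ipa_frac
            is_long = ~is_ipa & (rng.random(n_reads) < psi)
            pas = np.where(is_ipa, t["ipa_pas"],
                           np.where(is_long, t["dpas"], t["ppas"])).astype(np.int64)
            pos = pas + _trunc_normal_int(rng, cfg.cleavage_sd,
                                          cfg.cleavage_max, n_reads)
            n_t = rng.integers(cfg.true_T_range[0], cfg.true_T_range[1] + 1,
                               n_reads)
            mapq = np.where(rng.random(n_reads) < cfg.frac_low_mapq,
                            rng.integers(0, 10, n_reads), cfg.mapq_good)
            n_noise = rng.binomial(n_reads, cfg.noise_rate)
            if n_noise:
                npos = rng.integers(t["gene_start"], t["gene_end"], n_noise)
                nt = rng.integers(cfg.noise_T_range[0], cfg.noise_T_range[1] + 1,
                                  n_noise)
                pos = np.concatenate([pos, npos])
                n_t = np.concatenate([n_t, nt])
                mapq = np.concatenate([mapq, np.full(n_noise, cfg.mapq_good)])
            frames.append(pd.DataFrame({
                "chrom": t["chrom"], "position": pos, "strand": t["strand"],
                "mapq": mapq, "nongenomic_T": n_t, "sample": sample,
            }))
    df = pd.concat(frames, ignore_index=True)
    return df[READ_COLUMNS]


# ---------------------------------------------------------------------------
# bulk RNA-seq region counts


def simulate_rnaseq(
    genome: Genome,
    samples: Sequence[str] = ("ref", "test"),
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Poisson region counts (cUTR/aUTR/CDS) per gene, sample, replicate.

    Full-length coverage model: expected cUTR reads scale with cUTR
    length (every isoform covers it), aUTR reads with psi x aUTR length
    (long isoforms only), CDS reads with CDS length. The per-gene scale
    is set so the expected cUTR+aUTR reads in the reference sample equal
    ``region_reads_per_gene``; expression fold changes (test vs ref) act
    on all of a gene's regions alike.
    """
    cfg = genome.config
    truth = genome.truth
    rows = []
    for si, sample in enumerate(samples):
        rng = cfg.rng(200 + si)
        which = "ref" if si == 0 else "test"
        psi = truth[f"psi_{which}"].to_numpy()
        fc = np.exp2(truth["expr_log2fc"].to_numpy()) if which == "test" else 1.0
        base = cfg.region_reads_per_gene / (
            truth["cutr_len"] + truth["psi_ref"] * truth["autr_len"]
        ).to_numpy()
        for rep in range(1, n_replicates + 1):
            jitter = (np.exp(rng.normal(0.0, cfg.replicate_jitter_sd, len(truth)))
                      if n_replicates > 1 else 1.0)
            lam_c = base * truth["cutr_len"].to_numpy() * fc * jitter
            lam_a = base * psi * truth["autr_len"].to_numpy() * fc * jitter
            lam_g = base * truth["cds_len"].to_numpy() * fc * jitter
            rows.append(pd.DataFrame({
                "gene_id": truth.index, "sample": sample, "replicate": rep,
                "cutr": rng.poisson(lam_c), "autr": rng.poisson(lam_a),
                "cds": rng.poisson(lam_g),
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# single cells


@dataclass
class CellSim:
    counts: pd.DataFrame          # cells x genes UMI matrix
    clusters: pd.Series           # cell_id -> anonymous cluster label
    panel: pd.DataFrame           # gene_id, subtype
    region_counts: pd.DataFrame   # cell_id, gene_id, cutr, autr (3'-tag model)
    cell_truth: pd.DataFrame      # cell_id, subtype, u, psi


def simulate_cells(genome: Genome) -> CellSim:
    """Single cells with planted subtype markers and an APA gradient.

    Each cell gets a subtype and a differentiation coordinate u ~ U(0,1).
    Marker genes of the cell's subtype are amplified by
    marker_effect x (0.5 + u), so "far" (large-u) cells express their
    markers more. The cell's long-isoform fraction is
    psi_subtype - (u - 0.5) x psi_gradient, and per-cell region counts
    follow the 3'-tag model: aUTR reads ~ Binomial(reads, psi).
    """
    cfg = genome.config
    rng = cfg.rng(300)
    genes = list(genome.truth.index)
    subtypes = list(cfg.subtypes)
    marker_ids = {
        st: [f"MK_{st}_{j:02d}" for j in range(cfg.markers_per_subtype)]
        for st in subtypes
    }
    panel = pd.DataFrame(
        [{"gene_id": g, "subtype": st} for st in subtypes for g in marker_ids[st]]
    )
    all_genes = genes + [g for st in subtypes for g in marker_ids[st]]
    base = np.exp(rng.normal(0.0, cfg.expression_sigma, len(all_genes)))

    cells, rows_truth = [], []
    counts = np.zeros((cfg.cells_per_subtype * len(subtypes), len(all_genes)),
                      dtype=np.int64)
    marker_idx = {
        st: np.array([all_genes.index(g) for g in marker_ids[st]])
        for st in subtypes
    }
    i = 0
    for st_i, st in enumerate(subtypes):
        for c in range(cfg.cells_per_subtype):
            cell_id = f"{st_i}_{c:03d}"  # anonymous: no subtype name leaked
            u = rng.random()
            w = base.copy()
            w[marker_idx[st]] *= cfg.marker_effect * (0.5 + u)
            counts[i] = rng.multinomial(cfg.umis_per_cell, w / w.sum())
            psi = float(np.clip(cfg.psi_subtype[st] - (u - 0.5) * cfg.psi_gradient,
                                0.02, 0.98))
            cells.append(cell_id)
            rows_truth.append({"cell_id": cell_id, "subtype": st, "u": u,
                               "psi": psi, "cluster": f"k{st_i}"})
            i += 1
    counts_df = pd.DataFrame(counts, index=cells, columns=all_genes)
    cell_truth = pd.DataFrame(rows_truth).set_index("cell_id")

    # 3'-tag region counts: reads land at the isoform 3' end, so aUTR
    # reads report long isoforms and cUTR reads short ones.
    share = genome.truth["expression"].to_numpy()
    share = share / share.sum()
    lam = cfg.region_reads_per_cell * share  # per gene, per cell
    n_cells = len(cells)
    reads = cfg.rng(301).poisson(np.tile(lam, (n_cells, 1)))
    psi_cells = cell_truth["psi"].to_numpy()[:, None]
    autr = cfg.rng(302).binomial(reads, np.broadcast_to(psi_cells, reads.shape))
    cutr = reads - autr
    region_counts = pd.DataFrame({
        "cell_id": np.repeat(cells, len(genes)),
        "gene_id": np.tile(genes, n_cells),
        "cutr": cutr.ravel(),
        "autr": autr.ravel(),
    })
    clusters = cell_truth["cluster"].rename("cluster")
    return CellSim(counts_df, clusters, panel, region_counts, cell_truth)


# ---------------------------------------------------------------------------
# 4sU labeling


def simulate_4su(
    genome: Genome,
    reads_per_isoform: int | None = None,
    expectation: bool = False,
) -> pd.DataFrame:
    """Paired total/labeled counts per isoform under first-order decay.

    Steady-state abundance is proportional to synthesis x half-life; the
    labeled fraction after a pulse of ``label_time`` hours is
    1 - exp(-t*ln2/t_half). Expected total reads per isoform are set to
    ``reads_per_isoform``; labeled reads inherit the labeled fraction.
    ``expectation=True`` returns the exact expected values (no Poisson
    noise) for closed-form checks.
    """
    cfg = genome.config
    depth = cfg.reads_per_isoform if reads_per_isoform is None else reads_per_isoform
    rng = cfg.rng(400)
    rows = []
    for gene_id, t in genome.truth.iterrows():
        for isoform, t_half in (("short", t["t_half_short"]),
                                ("long", t["t_half_long"])):
            frac = 1.0 - np.exp(-cfg.label_time * np.log(2.0) / t_half)
            lam_total, lam_labeled = float(depth), float(depth * frac)
            if expectation:
                total, labeled = lam_total, lam_labeled
            else:
                total = int(rng.poisson(lam_total))
                labeled = int(rng.poisson(lam_labeled))
            rows.append({"gene_id": gene_id, "isoform": isoform,
                         "total": total, "labeled": labeled})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(
    n: int,
    length: int,
    seed: int,
    motif: str | None = None,
    planted_fraction: float = 0.0,
    copies: int = 1,
) -> list[str]:
    """Random DNA sequences, optionally with a motif planted in a fraction.

    Planted copies overwrite the sequence at uniform positions (they may
    overlap, so ``copies`` is an upper bound on distinct insertions).
    """
    rng = np.random.default_rng([seed, 500])
    seqs = []
    bases = np.array(list("ACGT"))
    for i in range(n):
        arr = rng.choice(bases, size=length)
        if motif and rng.random() < planted_fraction:
            for _ in range(copies):
                start = rng.integers(0, max(1, length - len(motif) + 1))
                arr[start:start + len(motif)] = list(motif)
        seqs.append("".join(arr))
    return seqs


def simulate_region_sequences(genome: Genome, motif: str = "TTTT",
                              density_per_kb: float = 3.0) -> pd.DataFrame:
    """cUTR/aUTR sequences; destabilizing motifs planted in aUTRs.

    The number of planted motif copies in a gene's aUTR grows with its
    aUTR length (density_per_kb copies per kb), mirroring the coupling of
    long aUTRs with destabilizing elements that the stability generator
    programs via its length-dependent half-life deficit.
    """
    cfg = genome.config
    rng = np.random.default_rng([cfg.seed, 501])
    bases = np.array(list("ACGT"))
    rows = []
    for gene_id, t in genome.truth.iterrows():
        cutr = "".join(rng.choice(bases, size=int(t["cutr_len"])))
        alen = int(t["autr_len"])
        arr = rng.choice(bases, size=alen)
        n_copies = int(np.floor(density_per_kb * alen / 1000.0))
        for _ in range(n_copies):
            start = rng.integers(0, max(1, alen - len(motif) + 1))
            arr[start:start + len(motif)] = list(motif)
        rows.append({"gene_id": gene_id, "cutr_seq": cutr,
                     "autr_seq": "".join(arr)})
    return pd.DataFrame(rows).set_index("gene_id")


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n{sequences[name]}\n")
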