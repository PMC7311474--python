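"""Sequence-motif and gene-set statistics.

Three families of analyses live here:

* **Tetramer enrichment** between two sequence sets (e.g. aUTRs of
  shortened genes vs aUTRs of other genes): for each of the 256 DNA
  4-mers a 2x2 table of sequences containing/not containing the motif is
  tested with Fisher's exact test and summarized as a signed -log10(p),
  positive when the motif is enriched in set A. An occurrence-count mode
  (total sliding-window hits vs windows) is available behind a flag.

* **Gene Ontology enrichment** by the upper-tail hypergeometric test,
  deliberately without multiple-testing adjustment, with two filters:
  generic terms annotating more than 1000 genes are discarded outright,
  and a term whose genes overlap a more significant kept term by more
  than 75% is discarded as redundant. The term->gene table is an input;
  no ontology is bundled.

* **Gene-set summaries**: distribution-shift tests (two-sided K-S and
  Wilcoxon rank-sum) of a per-gene statistic in a set vs background,
  construction of the intersection-based "upregulated in both models and
  annotated to the top terms" set (USPS), and sample-level Pearson
  correlation between APA REDs and set expression.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fisher_pvalue, hypergeom_upper_tail, ranksum_pvalue

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
TETRAMERS = tuple("".join(p) for p in itertools.product(ALPHABET, repeat=4))

MAX_TERM_SIZE = 1000
REDUNDANCY_OVERLAP = 0.75


# ---------------------------------------------------------------------------
# tetramers


def _kmers(seq: str, k: int = 4) -> Iterable[str]:
    seq = seq.upper().replace("U", "T")
    return (seq[i:i + k] for i in range(len(seq) - k + 1))


def tetramer_presence(sequences: Sequence[str]) -> pd.Series:
    """Number of sequences containing each tetramer at least once."""
    counts = dict.fromkeys(TETRAMERS, 0)
    for seq in sequences:
        for kmer in set(_kmers(seq)):
            if kmer in counts:
                counts[kmer] += 1
    return pd.Series(counts, name="n_with")


def tetramer_occurrences(sequences: Sequence[str]) -> tuple[pd.Series, int]:
    """Total sliding-window occurrences of each tetramer, plus window count."""
    counts = dict.fromkeys(TETRAMERS, 0)
    windows = 0
    for seq in sequences:
        for kmer in _kmers(seq):
            windows += 1
            if kmer in counts:
                counts[kmer] += 1
    return pd.Series(counts, name="occurrences"), windows


def tetramer_enrichment(
    set_a: Sequence[str],
    set_b: Sequence[str],
    mode: str = "presence",
) -> pd.DataFrame:
    """Signed -log10 Fisher p for each tetramer, set A vs set B.

    ``presence`` (default): the 2x2 counts sequences with/without the
    motif in each set. ``occurrence``: counts motif hits vs other windows
    (a per-nucleotide normalization). Scores are positive when the motif
    is over-represented in set A, zero at p = 1, and exactly antisymmetric
    under swapping the sets.
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    if mode == "presence":
        with_a = tetramer_presence(set_a)
        with_b = tetramer_presence(set_b)
        n_a, n_b = len(set_a), len(set_b)
    elif mode == "occurrence":
        with_a, n_a = tetramer_occurrences(set_a)
        with_b, n_b = tetramer_occurrences(set_b)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for kmer in TETRAMERS:
        a_w, b_w = int(with_a[kmer]), int(with_b[kmer])
        table = [[a_w, n_a - a_w], [b_w, n_b - b_w]]
        p = fisher_pvalue(table)
        frac_a = a_w / n_a if n_a else 0.0
        frac_b = b_w / n_b if n_b else 0.0
        sign = 1.0 if frac_a > frac_b else (-1.0 if frac_a < frac_b else 0.0)
        rows.append({
            "tetramer": kmer,
            "count_a_with": a_w, "count_a_without": n_a - a_w,
            "count_b_with": b_w, "count_b_without": n_b - b_w,
            "p_value": p,
            "score": sign * -np.log10(p) if p > 0 else sign * np.inf,
        })
    return pd.DataFrame(rows).set_index("tetramer")


def enrichment_correlation(scores_x: pd.Series | pd.DataFrame,
                           scores_y: pd.Series | pd.DataFrame) -> float:
    """Pearson r between two tetramer score vectors (NaN at zero variance)."""
    x = scores_x["score"] if isinstance(scores_x, pd.DataFrame) else scores_x
    y = scores_y["score"] if isinstance(scores_y, pd.DataFrame) else scores_y
    common = x.index.intersection(y.index)
    xv, yv = x.loc[common].to_numpy(float), y.loc[common].to_numpy(float)
    finite = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[finite], yv[finite]
    if len(xv) < 2 or xv.std() == 0 or yv.std() == 0:
        return float("nan")
    return float(stats.pearsonr(xv, yv).statistic)


def to_rna(tetramer: str) -> str:
    """Display helper: DNA 4-mer -> RNA alphabet (T -> U)."""
    return tetramer.replace("T", "U")


# ---------------------------------------------------------------------------
# GO enrichment


def _normalize_term_map(term_map) -> dict[str, frozenset]:
    if isinstance(term_map, pd.DataFrame):
        return {
            term: frozenset(grp["gene_id"])
            for term, grp in term_map.groupby("term_id")
        }
    return {t: frozenset(genes) for t, genes in term_map.items()}


def go_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    term_map,
    *,
    max_term_size: int = MAX_TERM_SIZE,
    redundancy_overlap: float = REDUNDANCY_OVERLAP,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with generic-term and redundancy filters.

    Per term: p = P[X >= overlap], X ~ Hypergeom(|universe|, term size in
    universe, |query|); no multiple-testing adjustment. Terms with more
    than ``max_term_size`` universe genes are discarded before testing.
    Remaining terms are ranked by (p, larger overlap first, term_id) and a
    term is dropped when the fraction of its genes shared with any more
    significant kept term exceeds ``redundancy_overlap``. Output is the
    full ranked table with a ``kept`` flag; the order is independent of
    input term order.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    terms = _normalize_term_map(term_map)
    rows = []
    for term_id in sorted(terms):
        genes = terms[term_id] & universe
        if not genes:
            logger.debug("go_enrich: term %s has no universe genes; skipped", term_id)
            continue
        if len(genes) > max_term_size:
            continue
        overlap = len(genes & query)
        p = hypergeom_upper_tail(overlap, len(universe), len(genes), len(query))
        rows.append({"term_id": term_id, "n_genes": len(genes),
                     "overlap": overlap, "p_value": p, "genes": genes})
    if not rows:
        return pd.DataFrame(columns=["term_id", "n_genes", "overlap",
                                     "p_value", "kept"]).set_index("term_id")
    df = pd.DataFrame(rows).sort_values(
        ["p_value", "overlap", "term_id"], ascending=[True, False, True],
        kind="mergesort",
    )
    kept_sets: list[frozenset] = []
    kept_flags = []
    for _, row in df.iterrows():
        genes = row["genes"]
        redundant = any(
            len(genes & k) / len(genes) > redundancy_overlap for k in kept_sets
        )
        kept_flags.append(not redundant)
        if not redundant:
            kept_sets.append(genes)
    df["kept"] = kept_flags
    return df.drop(columns="genes").set_index("term_id")


# ---------------------------------------------------------------------------
# USPS and shift tests


@dataclass(frozen=True)
class UspsSet:
    """Genes upregulated in both models and annotated to the top terms."""

    genes: frozenset
    top_terms: tuple[str, ...]
    common_up: frozenset


def define_usps(
    de_model_a: pd.DataFrame,
    de_model_b: pd.DataFrame,
    term_map,
    *,
    universe: Iterable[str] | None = None,
    n_top_terms: int = 3,
    max_term_size: int = MAX_TERM_SIZE,
    redundancy_overlap: float = REDUNDANCY_OVERLAP,
) -> UspsSet:
    """Intersect both models' upregulated genes, annotate to the top terms.

    The two DE tables (indexed by gene, with a ``call`` column) should
    come from the same thresholds. GO enrichment runs on the intersection
    against ``universe`` (default: genes tested in both models); the USPS
    set is the intersection restricted to genes of the top
    ``n_top_terms`` kept terms.
    """
    up_a = set(de_model_a.index[de_model_a["call"] == "up"])
    up_b = set(de_model_b.index[de_model_b["call"] == "up"])
    common = up_a & up_b
    if universe is None:
        universe = set(de_model_a.index) & set(de_model_b.index)
    universe = set(universe) | common
    enr = go_enrich(common, universe, term_map, max_term_size=max_term_size,
                    redundancy_overlap=redundancy_overlap)
    kept = enr[enr["kept"]]
    if len(kept) < n_top_terms:
        logger.warning("define_usps: only %d kept terms (< %d requested)",
                       len(kept), n_top_terms)
    top = tuple(kept.index[:n_top_terms])
    terms = _normalize_term_map(term_map)
    annotated = set().union(*(terms[t] for t in top)) if top else set()
    return UspsSet(frozenset(common & annotated), top, frozenset(common))


@dataclass(frozen=True)
class ShiftResult:
    ks_statistic: float
    ks_p: float
    wilcoxon_p: float
    direction: int  # sign of median(set) - median(background)


def geneset_shift(
    values: pd.Series,
    gene_set: Iterable[str],
    background: str = "others",
) -> ShiftResult:
    """Is the per-gene statistic shifted in the set vs the background?

    ``background='others'`` compares the set against all remaining genes
    (disjoint); ``'all'`` compares against the full distribution. Both a
    two-sided K-S test and a two-sided Wilcoxon rank-sum are reported.
    """
    gene_set = set(gene_set)
    in_set = values.loc[values.index.isin(gene_set)].dropna()
    if background == "others":
        bg = values.loc[~values.index.isin(gene_set)].dropna()
    elif background == "all":
        bg = values.dropna()
    else:
        raise ValueError(f"unknown background {background!r}")
    if in_set.empty or bg.empty:
        raise ValueError("empty gene set or background")
    ks = stats.ks_2samp(in_set, bg, alternative="two-sided")
    w_p = ranksum_pvalue(in_set, bg)
    diff = float(in_set.median() - bg.median())
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    return ShiftResult(float(ks.statistic), float(ks.pvalue), w_p, direction)


# ---------------------------------------------------------------------------
# RED vs expression correlation


def red_expression_correlation(sample_reds: pd.Series,
                               sample_expression: pd.Series) -> float:
    """Pearson r between sample-level REDs and gene-set expression means.

    Requires at least three samples; NaN on shorter input or zero
    variance.
    """
    common = sample_reds.index.intersection(sample_expression.index)
    if len(common) < 3:
        return float("nan")
    x = sample_reds.loc[common].to_numpy(float)
    y = sample_expression.loc[common].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def per_gene_red_correlation(
    red_matrix: pd.DataFrame,
    sample_expression: pd.Series,
    bottom_fraction: float = 0.05,
) -> tuple[pd.Series, pd.Index, float]:
    """Per-gene correlation of RED (genes x samples) with set expression.

    The exploratory screen: each gene's RED profile across samples is
    correlated with the per-sample expression summary; returns (per-gene
    r, the index of the most negatively correlated ``bottom_fraction`` of
    genes, the r threshold used).
    """
    common = red_matrix.columns.intersection(sample_expression.index)
    if len(common) < 3:
        raise ValueError("need at least three samples")
    expr = sample_expression.loc[common].to_numpy(float)
    rs = {}
    for gene, row in red_matrix[common].iterrows():
        v = row.to_numpy(float)
        ok = np.isfinite(v)
        if ok.sum() < 3 or v[ok].std() == 0 or expr[ok].std() == 0:
            rs[gene] = float("nan")
            continue
        rs[gene] = float(stats.pearsonr(v[ok], expr[ok]).statistic)
    r = pd.Series(rs, name="r")
    valid = r.dropna()
    if valid.empty:
        return r, pd.Index([]), float("nan")
    threshold = float(valid.quantile(bottom_fraction))
    return r, valid.index[valid <= threshold], threshold


# ---------------------------------------------------------------------------
# IO


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_term_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: term map needs term_id and gene_id columns")
    return df
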