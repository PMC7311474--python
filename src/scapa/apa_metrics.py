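"""Core APA statistics.

The central quantity is the Relative Expression Difference (RED): the
between-sample difference of a within-gene log2 isoform ratio. For
3'-end-sequencing data the ratio is distal over proximal PAS-read counts
of the gene's two most abundant last-exon 3'UTR isoforms; for RNA-seq it
is aUTR over cUTR read counts. Because the ratio is taken within a gene
and within a sample, sequencing depth cancels and no normalization enters
the RED itself. Negative RED = 3'UTR shortening.

Significance of an APA change in an unreplicated design comes from a
two-sided Fisher's exact test on the 2x2 raw-count table; replicated
designs use a Welch t-test on per-replicate log ratios (a documented
approximation of a negative-binomial isoform-ratio model). Two calling
dialects are supported: ``abundance5`` (default; absolute change of the
distal/long-isoform fraction > 5% and p < 0.05) and ``ratio20`` (isoform
expression ratio changed by more than 20% and p < 0.05).

Intronic polyadenylation (IPA) uses the same machinery with intronic
PAS reads as "long-indicating" numerator replaced: the ratio is IPA over
terminal-exon (TPA) reads, so a positive change means IPA activation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import annotation as ann
from ._stats import (PSEUDOCOUNT, bh_fdr, bootstrap_sem_median, fisher_pvalue,
                     log2_ratio, ranksum_pvalue)
from .pas_reads import PasCluster, size_factors

logger = logging.getLogger(__name__)

MIN_READS = 5          # per compared isoform/region, summed over the two samples
SIG_RULES = ("abundance5", "ratio20")

SHORTENED, LENGTHENED, UNCHANGED = "shortened", "lengthened", "unchanged"
ACTIVATED, SUPPRESSED = "activated", "suppressed"


@dataclass(frozen=True)
class IsoformPair:
    """The two most abundant last-exon 3'UTR isoforms of one gene.

    ``counts`` maps sample -> (proximal, distal) PAS-read counts; the
    proximal site is 5' of the distal site in transcript orientation.
    """

    gene_id: str
    ppas_position: int
    dpas_position: int
    counts: Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class ApaResult:
    gene_id: str
    red: float
    p_value: float
    abundance_change: float
    call: str
    sd: float | None = None


@dataclass(frozen=True)
class IpaResult:
    gene_id: str
    ipa_counts: Mapping[str, int]
    tpa_counts: Mapping[str, int]
    log2_ratio_change: float
    p_value: float
    abundance_change: float
    call: str


@dataclass(frozen=True)
class DirectionTally:
    n_shortened: int
    n_lengthened: int
    n_unchanged: int

    @property
    def ratio(self) -> float:
        """shortened / lengthened; NaN when the denominator is zero."""
        if self.n_lengthened == 0:
            return float("nan")
        return self.n_shortened / self.n_lengthened


# ---------------------------------------------------------------------------
# isoform selection


def select_top2(
    clusters: Sequence[PasCluster],
    ref: str,
    test: str,
    min_reads: int = MIN_READS,
) -> IsoformPair | None:
    """Pick a gene's two most abundant eligible 3'UTR clusters.

    A cluster is eligible if its reads summed over the two samples reach
    ``min_reads``. The two highest pooled-count clusters are chosen (ties
    to the 5'-most) and labelled proximal/distal by transcript-orientation
    order. Returns None (gene excluded) when fewer than two clusters are
    eligible.
    """
    if not clusters:
        return None
    strand = clusters[0].strand
    orient = (lambda p: p) if strand == "+" else (lambda p: -p)
    eligible = [
        c for c in clusters
        if c.counts.get(ref, 0) + c.counts.get(test, 0) >= min_reads
    ]
    if len(eligible) < 2:
        return None
    top2 = sorted(
        eligible,
        key=lambda c: (-(c.counts.get(ref, 0) + c.counts.get(test, 0)),
                       orient(c.representative)),
    )[:2]
    prox, dist = sorted(top2, key=lambda c: orient(c.representative))
    gene_id = getattr(top2[0], "gene_id", "") or ""
    counts = {
        s: (int(prox.counts.get(s, 0)), int(dist.counts.get(s, 0)))
        for s in (ref, test)
    }
    return IsoformPair(gene_id, prox.representative, dist.representative, counts)


# ---------------------------------------------------------------------------
# RED


def _is_significant(red: float, p: float, abundance_change: float, *,
                    sig_rule: str, alpha: float, min_change: float,
                    min_ratio_change: float) -> bool:
    if sig_rule == "abundance5":
        return p < alpha and abs(abundance_change) > min_change
    if sig_rule == "ratio20":
        return p < alpha and abs(red) > math.log2(1.0 + min_ratio_change)
    raise ValueError(f"unknown sig_rule {sig_rule!r}; choose from {SIG_RULES}")


def _ratio_change(ref_pair: tuple[float, float], test_pair: tuple[float, float],
                  *, sig_rule: str, alpha: float, min_change: float,
                  min_ratio_change: float):
    """Shared core: log2-ratio change, Fisher p, fraction change, call sign."""
    s_ref, l_ref = ref_pair   # short-indicating, long-indicating counts
    s_test, l_test = test_pair
    red = log2_ratio(l_test, s_test) - log2_ratio(l_ref, s_ref)
    table = [[s_ref, l_ref], [s_test, l_test]]
    p = fisher_pvalue(table)
    tot_ref, tot_test = s_ref + l_ref, s_test + l_test
    if tot_ref == 0 or tot_test == 0:
        return red, 1.0, 0.0, False
    change = l_test / tot_test - l_ref / tot_ref
    sig = _is_significant(red, p, change, sig_rule=sig_rule, alpha=alpha,
                          min_change=min_change,
                          min_ratio_change=min_ratio_change)
    return red, p, change, sig


def red_3reads(
    pair: IsoformPair,
    ref: str,
    test: str,
    *,
    sig_rule: str = "abundance5",
    alpha: float = 0.05,
    min_change: float = 0.05,
    min_ratio_change: float = 0.20,
) -> ApaResult:
    """RED and direction call for one gene from 3'-end-sequencing counts.

    RED = log2((dPAS+0.5)/(pPAS+0.5)) in ``test`` minus the same in
    ``ref``; within-gene ratios make depth normalization cancel. p comes
    from Fisher's exact test on the raw 2x2 table; the abundance change is
    the change in distal fraction dPAS/(pPAS+dPAS).
    """
    red, p, change, sig = _ratio_change(
        pair.counts[ref], pair.counts[test], sig_rule=sig_rule, alpha=alpha,
        min_change=min_change, min_ratio_change=min_ratio_change,
    )
    if sig and red < 0:
        call = SHORTENED
    elif sig and red > 0:
        call = LENGTHENED
    else:
        call = UNCHANGED
    return ApaResult(pair.gene_id, red, p, change, call)


def red_rnaseq(
    ref,
    test,
    *,
    gene_id: str = "",
    sig_rule: str = "abundance5",
    alpha: float = 0.05,
    min_change: float = 0.05,
    min_ratio_change: float = 0.20,
    n_boot: int = 20,
    seed: int | None = 0,
) -> ApaResult:
    """RED from RNA-seq cUTR/aUTR region counts.

    ``ref`` and ``test`` are (cUTR, aUTR) count pairs, or arrays of such
    pairs when replicates exist. Unreplicated: RED from pooled-free single
    counts, p from Fisher on the 2x2, SD from ``n_boot`` multinomial
    resamples of each sample's (cUTR, aUTR) reads. Replicated: RED is the
    difference of mean per-replicate log ratios and p a two-sided Welch
    t-test on them.
    """
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    test = np.atleast_2d(np.asarray(test, dtype=float))
    if ref.shape[0] == 1 and test.shape[0] == 1:
        (c_ref, a_ref), (c_test, a_test) = ref[0], test[0]
        red, p, change, sig = _ratio_change(
            (c_ref, a_ref), (c_test, a_test), sig_rule=sig_rule, alpha=alpha,
            min_change=min_change, min_ratio_change=min_ratio_change,
        )
        sd = _bootstrap_red_sd((c_ref, a_ref), (c_test, a_test), n_boot, seed)
    else:
        r_ref = np.log2((ref[:, 1] + PSEUDOCOUNT) / (ref[:, 0] + PSEUDOCOUNT))
        r_test = np.log2((test[:, 1] + PSEUDOCOUNT) / (test[:, 0] + PSEUDOCOUNT))
        red = float(r_test.mean() - r_ref.mean())
        p = float(stats.ttest_ind(r_test, r_ref, equal_var=False).pvalue)
        if math.isnan(p):  # zero variance in both groups
            p = 1.0 if red == 0 else 0.0
        c_ref, a_ref = ref.sum(axis=0)
        c_test, a_test = test.sum(axis=0)
        change = (a_test / (a_test + c_test) if a_test + c_test else 0.0) - (
            a_ref / (a_ref + c_ref) if a_ref + c_ref else 0.0)
        sd = float(np.sqrt(r_test.var(ddof=1) / len(r_test)
                           + r_ref.var(ddof=1) / len(r_ref)))
        sig = _is_significant(red, p, change, sig_rule=sig_rule, alpha=alpha,
                              min_change=min_change,
                              min_ratio_change=min_ratio_change)
    if sig and red < 0:
        call = SHORTENED
    elif sig and red > 0:
        call = LENGTHENED
    else:
        call = UNCHANGED
    return ApaResult(gene_id, red, p, change, call, sd)


def _bootstrap_red_sd(ref_pair, test_pair, n_boot: int, seed) -> float:
    rng = np.random.default_rng(seed)
    n_ref = int(round(ref_pair[0] + ref_pair[1]))
    n_test = int(round(test_pair[0] + test_pair[1]))
    if n_ref == 0 or n_test == 0 or n_boot < 2:
        return float("nan")
    p_ref = np.asarray(ref_pair, dtype=float) / n_ref
    p_test = np.asarray(test_pair, dtype=float) / n_test
    b_ref = rng.multinomial(n_ref, p_ref, size=n_boot)
    b_test = rng.multinomial(n_test, p_test, size=n_boot)
    reds = (np.log2((b_test[:, 1] + PSEUDOCOUNT) / (b_test[:, 0] + PSEUDOCOUNT))
            - np.log2((b_ref[:, 1] + PSEUDOCOUNT) / (b_ref[:, 0] + PSEUDOCOUNT)))
    return float(reds.std(ddof=1))


# ---------------------------------------------------------------------------
# IPA


def ipa_analysis(
    ipa_counts: Mapping[str, int],
    tpa_counts: Mapping[str, int],
    ref: str,
    test: str,
    *,
    gene_id: str = "",
    sig_rule: str = "abundance5",
    alpha: float = 0.05,
    min_change: float = 0.05,
    min_ratio_change: float = 0.20,
    min_reads: int = MIN_READS,
) -> IpaResult | None:
    """Compare summed intronic (IPA) vs last-exon (TPA) PAS reads.

    Returns None when either isoform class fails the read guard. A
    significant increase of the IPA fraction calls "activated".
    """
    ipa_ref, ipa_test = int(ipa_counts.get(ref, 0)), int(ipa_counts.get(test, 0))
    tpa_ref, tpa_test = int(tpa_counts.get(ref, 0)), int(tpa_counts.get(test, 0))
    if ipa_ref + ipa_test < min_reads or tpa_ref + tpa_test < min_reads:
        return None
    change_l2, p, change, sig = _ratio_change(
        (tpa_ref, ipa_ref), (tpa_test, ipa_test), sig_rule=sig_rule,
        alpha=alpha, min_change=min_change, min_ratio_change=min_ratio_change,
    )
    if sig and change_l2 > 0:
        call = ACTIVATED
    elif sig and change_l2 < 0:
        call = SUPPRESSED
    else:
        call = UNCHANGED
    return IpaResult(gene_id, {ref: ipa_ref, test: ipa_test},
                     {ref: tpa_ref, test: tpa_test}, change_l2, p, change, call)


# ---------------------------------------------------------------------------
# summaries


def bin_by_autr(
    metric: pd.Series,
    autr_length: pd.Series,
    n_bins: int = 5,
    n_boot: int = 100,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, float]:
    """Group genes into near-equal aUTR-length bins; summarize the metric.

    Genes are sorted by aUTR length and cut into ``n_bins`` groups of near
    equal size (tied lengths stay together in the lower bin). Each bin
    reports its size, length range, median metric and a bootstrap SEM of
    the median. Returns (bin table, Wilcoxon rank-sum p between the first
    and last bins).
    """
    common = metric.index.intersection(autr_length.index)
    if len(common) < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {len(common)}")
    df = pd.DataFrame({"metric": metric.loc[common],
                       "length": autr_length.loc[common]})
    df = df.sort_values(["length"], kind="mergesort")
    n = len(df)
    bins = np.floor(np.arange(n) * n_bins / n).astype(int)
    # keep tied lengths together in the lower bin
    lengths = df["length"].to_numpy()
    for i in range(1, n):
        if lengths[i] == lengths[i - 1]:
            bins[i] = bins[i - 1]
    df["bin"] = bins + 1

    rng = np.random.default_rng(seed)
    rows = []
    for b, sub in df.groupby("bin"):
        rows.append({
            "bin": int(b),
            "n": len(sub),
            "min_autr": float(sub["length"].min()),
            "max_autr": float(sub["length"].max()),
            "median": float(sub["metric"].median()),
            "sem": bootstrap_sem_median(sub["metric"], n_boot=n_boot, rng=rng),
        })
    table = pd.DataFrame(rows).set_index("bin")
    first = df.loc[df["bin"] == table.index.min(), "metric"]
    last = df.loc[df["bin"] == table.index.max(), "metric"]
    return table, ranksum_pvalue(first, last)


def tally_direction(calls: Iterable[str]) -> DirectionTally:
    """Count shortened/lengthened/unchanged calls (IPA calls map onto them)."""
    n_s = n_l = n_u = 0
    for c in calls:
        if c in (SHORTENED, SUPPRESSED):
            n_s += 1
        elif c in (LENGTHENED, ACTIVATED):
            n_l += 1
        else:
            n_u += 1
    return DirectionTally(n_s, n_l, n_u)


def normalize_red(values, mode: str = "mean"):
    """Center RED values on their mean or median across samples."""
    v = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if len(v) < 2:
        raise ValueError("normalize_red needs at least two samples")
    if mode == "mean":
        return v - v.mean()
    if mode == "median":
        return v - v.median()
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# minimal differential expression


def diff_expression(
    counts: pd.DataFrame,
    ref: Sequence[str],
    test: Sequence[str],
    fc_threshold: float = 1.2,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-level expression comparison on coding-region counts.

    Counts are size-factor normalized (median-of-ratios). Without
    replicates, per-gene p-values come from Fisher's exact test of the
    gene's raw counts against the rest of each library; with replicates,
    from a Welch t-test on log2 normalized counts. Calls use
    Benjamini-Hochberg FDR and the fold-change threshold.
    """
    ref, test = list(ref), list(test)
    sub = counts[ref + test]
    sf = size_factors(sub)
    norm = sub / sf
    mean_ref = norm[ref].mean(axis=1)
    mean_test = norm[test].mean(axis=1)
    log2fc = np.log2((mean_test + PSEUDOCOUNT) / (mean_ref + PSEUDOCOUNT))

    if len(ref) == 1 and len(test) == 1:
        raw_ref = sub[ref[0]]
        raw_test = sub[test[0]]
        lib_ref, lib_test = int(raw_ref.sum()), int(raw_test.sum())
        pvals = np.array([
            fisher_pvalue([[int(r), lib_ref - int(r)], [int(t), lib_test - int(t)]])
            for r, t in zip(raw_ref, raw_test)
        ])
    else:
        log_norm = np.log2(norm + PSEUDOCOUNT)
        res = stats.ttest_ind(log_norm[test], log_norm[ref], axis=1,
                              equal_var=False)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)

    fdr = bh_fdr(pvals)
    thr = math.log2(fc_threshold)
    call = np.where((fdr < fdr_alpha) & (log2fc > thr), "up",
                    np.where((fdr < fdr_alpha) & (log2fc < -thr), "down",
                             "unchanged"))
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "fdr": fdr, "call": call},
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# drivers over clustered counts


def assign_clusters(
    clusters: Sequence[PasCluster],
    models: Mapping[str, ann.GeneModel],
) -> pd.DataFrame:
    """Place cluster representatives on gene models.

    Returns one row per cluster (index: cluster order) with gene_id,
    location_class and the cluster object itself.
    """
    sites = [(c.chrom, c.representative, c.strand) for c in clusters]
    annos = ann.classify_pas(models, sites)
    return pd.DataFrame({
        "gene_id": [a.gene_id for a in annos],
        "location_class": [a.location_class for a in annos],
        "cluster": list(clusters),
    })


def apa_3utr_analysis(
    clusters: Sequence[PasCluster],
    models: Mapping[str, ann.GeneModel],
    ref: str,
    test: str,
    *,
    min_reads: int = MIN_READS,
    sig_rule: str = "abundance5",
    alpha: float = 0.05,
    min_change: float = 0.05,
    min_ratio_change: float = 0.20,
) -> pd.DataFrame:
    """Per-gene 3'UTR APA table (top-2 isoforms) from clustered counts."""
    placed = assign_clusters(clusters, models)
    utr3 = placed[placed["location_class"] == ann.UTR3]
    rows = []
    for gene_id, grp in utr3.groupby("gene_id", sort=True):
        pair = select_top2(list(grp["cluster"]), ref, test, min_reads=min_reads)
        if pair is None:
            logger.debug("gene %s: <2 eligible 3'UTR clusters", gene_id)
            continue
        pair = IsoformPair(gene_id, pair.ppas_position, pair.dpas_position,
                           pair.counts)
        res = red_3reads(pair, ref, test, sig_rule=sig_rule, alpha=alpha,
                         min_change=min_change,
                         min_ratio_change=min_ratio_change)
        p_ref, d_ref = pair.counts[ref]
        p_test, d_test = pair.counts[test]
        rows.append({
            "gene_id": gene_id,
            "ppas": pair.ppas_position,
            "dpas": pair.dpas_position,
            f"ppas_{ref}": p_ref, f"dpas_{ref}": d_ref,
            f"ppas_{test}": p_test, f"dpas_{test}": d_test,
            "red": res.red,
            "p_value": res.p_value,
            "abundance_change": res.abundance_change,
            "call": res.call,
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()


def ipa_gene_analysis(
    clusters: Sequence[PasCluster],
    models: Mapping[str, ann.GeneModel],
    ref: str,
    test: str,
    *,
    min_reads: int = MIN_READS,
    sig_rule: str = "abundance5",
    alpha: float = 0.05,
    min_change: float = 0.05,
    min_ratio_change: float = 0.20,
) -> pd.DataFrame:
    """Per-gene IPA-vs-TPA table from clustered counts.

    Intronic clusters are summed into the IPA class; last-exon clusters
    (the gene's terminal-exon isoforms, including both 3'UTR PASs) into
    the TPA class.
    """
    placed = assign_clusters(clusters, models)
    rows = []
    for gene_id, grp in placed[placed["gene_id"].notna()].groupby("gene_id", sort=True):
        ipa: dict[str, int] = {ref: 0, test: 0}
        tpa: dict[str, int] = {ref: 0, test: 0}
        for _, row in grp.iterrows():
            target = ipa if row["location_class"] == ann.INTRONIC else (
                tpa if row["location_class"] == ann.UTR3 else None)
            if target is None:
                continue
            for s in (ref, test):
                target[s] += int(row["cluster"].counts.get(s, 0))
        res = ipa_analysis(ipa, tpa, ref, test, gene_id=gene_id,
                           sig_rule=sig_rule, alpha=alpha,
                           min_change=min_change,
                           min_ratio_change=min_ratio_change,
                           min_reads=min_reads)
        if res is None:
            continue
        rows.append({
            "gene_id": gene_id,
            f"ipa_{ref}": ipa[ref], f"ipa_{test}": ipa[test],
            f"tpa_{ref}": tpa[ref], f"tpa_{test}": tpa[test],
            "log2_ratio_change": res.log2_ratio_change,
            "p_value": res.p_value,
            "abundance_change": res.abundance_change,
            "call": res.call,
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
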