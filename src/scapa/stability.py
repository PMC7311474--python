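"""Transcript stability from paired total / metabolically-labeled counts.

A short metabolic-labeling pulse (4sU, 1 h by default) marks newly made
RNA. At steady state an isoform's abundance is k_syn * t_half / ln2 while
the labeled fraction after a pulse of length t is 1 - exp(-t*ln2/t_half),
so the log2 ratio of steady-state to newly-made abundance — the
Stability Score — is a monotone readout of half-life:

    score = -log2(1 - exp(-t * ln2 / t_half)) + constant

The additive constant absorbs labeling/recovery efficiency and
sequencing-depth differences between the two fractions (each fraction is
RPM-normalized separately); scores are therefore comparable within an
experiment and, in particular, between isoforms of the same gene, where
the constant cancels exactly. The per-gene contrast is
score(long 3'UTR isoform) - score(short isoform); negative means the long
isoform is less stable. The same contrast applies to IPA vs TPA isoforms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import PSEUDOCOUNT, bh_fdr, fisher_pvalue
from .apa_metrics import MIN_READS, bin_by_autr

LONG_LESS_STABLE = "long_less_stable"
SHORT_LESS_STABLE = "short_less_stable"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class StabilityTally:
    n_long_less_stable: int
    n_short_less_stable: int
    n_unchanged: int

    @property
    def ratio(self) -> float:
        if self.n_short_less_stable == 0:
            return float("nan")
        return self.n_long_less_stable / self.n_short_less_stable


def stability_score(
    counts: pd.DataFrame,
    *,
    total_col: str = "total",
    labeled_col: str = "labeled",
    min_reads: int = MIN_READS,
    total_depth: float | None = None,
    labeled_depth: float | None = None,
) -> pd.DataFrame:
    """Per-isoform Stability Scores.

    ``counts`` has one row per isoform with columns ``gene_id``,
    ``isoform`` (e.g. short/long or TPA/IPA) and raw counts in the total
    and labeled fractions. Depths default to the column sums of the full
    input (computed before any filtering, so the guard does not shift the
    normalization). The pseudocount is applied to the raw counts before
    the per-fraction RPM normalization:

        score = log2( ((total+0.5)/depth_total) / ((labeled+0.5)/depth_labeled) )

    Isoforms whose total+labeled reads fall below ``min_reads`` are
    dropped (no record).
    """
    for col in ("gene_id", "isoform", total_col, labeled_col):
        if col not in counts.columns:
            raise ValueError(f"counts is missing column {col!r}")
    d_tot = float(counts[total_col].sum()) if total_depth is None else float(total_depth)
    d_lab = float(counts[labeled_col].sum()) if labeled_depth is None else float(labeled_depth)
    if d_tot <= 0 or d_lab <= 0:
        raise ValueError("fraction depths must be positive")
    keep = (counts[total_col] + counts[labeled_col]) >= min_reads
    out = counts.loc[keep, ["gene_id", "isoform"]].copy()
    tot = counts.loc[keep, total_col].astype(float)
    lab = counts.loc[keep, labeled_col].astype(float)
    out["rpm_total"] = tot * 1e6 / d_tot
    out["rpm_labeled"] = lab * 1e6 / d_lab
    out["total"] = tot
    out["labeled"] = lab
    out["score"] = np.log2(((tot + PSEUDOCOUNT) / d_tot)
                           / ((lab + PSEUDOCOUNT) / d_lab))
    return out.reset_index(drop=True)


def center_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Subtract the median score (optional; removes the global offset)."""
    out = records.copy()
    out["score"] = out["score"] - out["score"].median()
    return out


def contrast_isoforms(
    records: pd.DataFrame,
    *,
    short_label: str = "short",
    long_label: str = "long",
    alpha: float = 0.05,
    use_fdr: bool = True,
) -> tuple[pd.DataFrame, StabilityTally]:
    """Long-minus-short Stability Score contrast per gene.

    For each gene scored in both isoforms: delta = score_long -
    score_short; p from Fisher's exact test on the raw 2x2
    (short, long) x (total, labeled) table; BH FDR across genes. A gene is
    called ``long_less_stable`` when delta < 0 and the (FDR-adjusted by
    default) p-value clears ``alpha``.
    """
    wide = records.set_index(["gene_id", "isoform"])
    rows = []
    for gene_id in sorted(records["gene_id"].unique()):
        try:
            short = wide.loc[(gene_id, short_label)]
            long_ = wide.loc[(gene_id, long_label)]
        except KeyError:
            continue
        delta = float(long_["score"] - short["score"])
        p = fisher_pvalue([[short["total"], short["labeled"]],
                           [long_["total"], long_["labeled"]]])
        rows.append({"gene_id": gene_id, "delta": delta, "p_value": p})
    if not rows:
        return pd.DataFrame(), StabilityTally(0, 0, 0)
    df = pd.DataFrame(rows).set_index("gene_id")
    df["fdr"] = bh_fdr(df["p_value"])
    crit = df["fdr"] if use_fdr else df["p_value"]
    df["call"] = np.where((crit < alpha) & (df["delta"] < 0), LONG_LESS_STABLE,
                          np.where((crit < alpha) & (df["delta"] > 0),
                                   SHORT_LESS_STABLE, UNCHANGED))
    tally = StabilityTally(
        int((df["call"] == LONG_LESS_STABLE).sum()),
        int((df["call"] == SHORT_LESS_STABLE).sum()),
        int((df["call"] == UNCHANGED).sum()),
    )
    return df, tally


def stability_by_autr(
    contrasts: pd.DataFrame,
    autr_length: pd.Series,
    n_bins: int = 5,
    n_boot: int = 100,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, float]:
    """Bin the long-minus-short score difference by aUTR length."""
    return bin_by_autr(contrasts["delta"], autr_length, n_bins=n_bins,
                       n_boot=n_boot, seed=seed)


def expected_score(t_half: float | np.ndarray, label_time: float = 1.0):
    """Closed-form Stability Score (up to an additive constant).

    First-order decay: -log2(1 - exp(-label_time * ln2 / t_half)).
    """
    t_half = np.asarray(t_half, dtype=float)
    frac = 1.0 - np.exp(-label_time * np.log(2.0) / t_half)
    return -np.log2(frac)
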