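"""Pseudo-bulk single-cell APA (scSAAP).

Single cells carry too few reads for per-cell APA statistics, so cells
are grouped (cluster labels are an input, typically from a standard
graph-clustering tool; a k-means-on-marker-scores fallback is provided),
each cluster is assigned a cell subtype by a marker-gene panel, cells of
a subtype are optionally split into "near" and "far" halves by their own
marker score (a deterministic surrogate for trajectory distance from the
lineage origin: more differentiated cells express their subtype's markers
more highly), and reads of all cells in a group are summed into a
pseudo-bulk sample on which the bulk cUTR/aUTR RED statistics run
unchanged.

Marker panels follow a strict reproducibility rule: a gene enters the
panel only if at least two independent studies assign it the same
subtype and no study assigns it a different one.

Note on region counts: with 3'-biased single-cell protocols reads pile
up at the transcript 3' end, so aUTR reads report long isoforms and
cUTR reads short isoforms; the aUTR/cUTR RED then estimates the change
in log2 isoform odds rather than log2 long-isoform fraction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import PSEUDOCOUNT
from .apa_metrics import MIN_READS, normalize_red

logger = logging.getLogger(__name__)

NEAR, FAR = "near", "far"
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# marker panel


def build_marker_panel(study_tables: Mapping[str, Mapping[str, str]] | Sequence) -> pd.DataFrame:
    """Consensus marker panel from per-study gene -> subtype tables.

    ``study_tables`` maps study name -> {gene: subtype} (or is a sequence
    of such mappings / DataFrames with gene_id and subtype columns). A
    gene is included iff at least two studies agree on one subtype and no
    study assigns a different one. Returns a DataFrame (gene_id, subtype,
    n_studies, studies) sorted by subtype then gene; exclusions are
    logged with their reason.
    """
    named = _normalize_studies(study_tables)
    if len(named) < 2:
        raise ValueError("need at least two study tables")
    votes: dict[str, list[tuple[str, str]]] = {}
    for study, table in named.items():
        for gene, subtype in table.items():
            votes.setdefault(gene, []).append((study, subtype))
    rows = []
    for gene in sorted(votes):
        labels = {subtype for _, subtype in votes[gene]}
        if len(labels) > 1:
            logger.debug("panel: %s excluded (conflicting subtypes %s)",
                         gene, sorted(labels))
            continue
        if len(votes[gene]) < 2:
            logger.debug("panel: %s excluded (<2 supporting studies)", gene)
            continue
        rows.append({
            "gene_id": gene,
            "subtype": labels.pop(),
            "n_studies": len(votes[gene]),
            "studies": ",".join(sorted(s for s, _ in votes[gene])),
        })
    panel = pd.DataFrame(rows, columns=["gene_id", "subtype", "n_studies", "studies"])
    return panel.sort_values(["subtype", "gene_id"]).reset_index(drop=True)


def _normalize_studies(study_tables) -> dict[str, dict[str, str]]:
    if isinstance(study_tables, Mapping):
        items = list(study_tables.items())
    else:
        items = [(f"study{i + 1}", t) for i, t in enumerate(study_tables)]
    out = {}
    for name, table in items:
        if isinstance(table, pd.DataFrame):
            out[name] = dict(zip(table["gene_id"], table["subtype"]))
        else:
            out[name] = dict(table)
    return out


def read_panel_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# normalization and scoring


def normalize_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-10k then log1p, per cell (rows = cells, cols = genes)."""
    depth = counts.sum(axis=1)
    if (depth == 0).any():
        raise ValueError("cells with zero counts; remove them first")
    return np.log1p(counts.div(depth, axis=0) * 1e4)


def subtype_scores(norm: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean normalized expression of each subtype's markers."""
    scores = {}
    detected = 0
    for subtype, grp in panel.groupby("subtype"):
        genes = [g for g in grp["gene_id"] if g in norm.columns]
        detected += len(genes)
        scores[subtype] = (norm[genes].mean(axis=1) if genes
                           else pd.Series(0.0, index=norm.index))
    if detected == 0:
        logger.warning("subtype_scores: no panel gene detected in the matrix")
    return pd.DataFrame(scores)


# ---------------------------------------------------------------------------
# assignment


def assign_subtypes(
    counts: pd.DataFrame,
    panel: pd.DataFrame,
    clusters: pd.Series | None = None,
    *,
    margin: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign cell clusters (hence cells) to subtypes by marker scores.

    ``clusters`` maps cell_id -> cluster label; when None, cells are
    k-means clustered on their subtype-score vectors (k = number of
    subtypes, seeded). Each cluster's mean score vector is computed; the
    cluster's subtype is the argmax unless the top two scores are within
    ``margin`` of each other, in which case it is left unassigned. All
    member cells inherit the cluster call.
    """
    norm = normalize_cells(counts)
    scores = subtype_scores(norm, panel)
    if clusters is None:
        from sklearn.cluster import KMeans

        k = scores.shape[1]
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        clusters = pd.Series(km.fit_predict(scores.to_numpy()),
                             index=scores.index, name="cluster")
    else:
        clusters = clusters.reindex(scores.index)
        if clusters.isna().any():
            raise ValueError("cluster labels missing for some cells")

    cluster_scores = scores.groupby(clusters).mean()
    subtype_of_cluster: dict = {}
    for cl, row in cluster_scores.iterrows():
        ordered = row.sort_values(ascending=False)
        if len(ordered) > 1 and ordered.iloc[0] - ordered.iloc[1] <= margin:
            subtype_of_cluster[cl] = UNASSIGNED
        else:
            subtype_of_cluster[cl] = ordered.index[0]

    out = scores.copy()
    out.insert(0, "cluster", clusters)
    out.insert(1, "subtype", clusters.map(subtype_of_cluster))
    own = []
    for cell, row in out.iterrows():
        st = row["subtype"]
        own.append(float(scores.at[cell, st]) if st != UNASSIGNED else float("nan"))
    out["own_score"] = own
    out["nearfar"] = pd.NA
    return out


def split_near_far(assignments: pd.DataFrame) -> pd.DataFrame:
    """Split each subtype into equal-size near/far halves by own score.

    Cells with a higher own-subtype marker score are "far" (more
    differentiated); an odd cell count puts the extra cell in "near".
    Ties are broken by cell_id for determinism.
    """
    out = assignments.copy()
    for subtype, grp in out.groupby("subtype"):
        if subtype == UNASSIGNED:
            continue
        if len(grp) < 2:
            raise ValueError(f"subtype {subtype}: need >=2 cells to split")
        order = grp.iloc[
            np.lexsort((np.asarray(grp.index.astype(str)),
                        -grp["own_score"].to_numpy()))
        ]
        n_far = len(order) // 2
        out.loc[order.index[:n_far], "nearfar"] = FAR
        out.loc[order.index[n_far:], "nearfar"] = NEAR
    return out


# ---------------------------------------------------------------------------
# aggregation


def aggregate(
    membership: pd.Series,
    region_counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum per-cell region counts into pseudo-bulk groups.

    ``membership`` maps cell_id -> group label; ``region_counts`` is long
    form with columns cell_id, gene_id, cutr, autr. Returns (counts summed
    per (group, gene), n_cells per group). Counts are exact integer sums.
    """
    membership = membership.dropna()
    n_cells = membership.value_counts().sort_index()
    if (n_cells == 0).any() or n_cells.empty:
        raise ValueError("empty pseudo-bulk group")
    df = region_counts.copy()
    df["group"] = df["cell_id"].map(membership)
    df = df.dropna(subset=["group"])
    agg = df.groupby(["group", "gene_id"])[["cutr", "autr"]].sum()
    missing = set(n_cells.index) - set(agg.index.get_level_values("group"))
    if missing:
        raise ValueError(f"groups without any region counts: {sorted(missing)}")
    return agg, n_cells


# ---------------------------------------------------------------------------
# scSAAP driver


@dataclass
class ScsaapResult:
    assignments: pd.DataFrame
    per_gene: pd.DataFrame      # genes x groups RED matrix
    summary: pd.DataFrame       # per-group n_cells, n_genes, median/centered RED


def scsaap(
    counts: pd.DataFrame,
    region_counts: pd.DataFrame,
    panel: pd.DataFrame,
    clusters: pd.Series | None = None,
    *,
    split: bool = False,
    margin: float = 0.0,
    seed: int = 0,
    min_reads: int = MIN_READS,
    center: str = "mean",
) -> ScsaapResult:
    """Assign -> (split) -> aggregate -> per-group RED against pooled cells.

    Each group's per-gene RED is its log2(aUTR/cUTR) minus the same ratio
    in the pool of all assigned cells (the common reference), so group
    REDs are directly comparable; the per-group median REDs are then
    centered on their mean (or median) across groups.
    """
    assignments = assign_subtypes(counts, panel, clusters, margin=margin, seed=seed)
    if split:
        assignments = split_near_far(assignments)
        assigned = assignments[assignments["subtype"] != UNASSIGNED]
        membership = assigned["subtype"].astype(str) + "_" + assigned["nearfar"].astype(str)
    else:
        assigned = assignments[assignments["subtype"] != UNASSIGNED]
        membership = assigned["subtype"]
    agg, n_cells = aggregate(membership, region_counts)

    pooled = agg.groupby("gene_id")[["cutr", "autr"]].sum()
    ref_ok = (pooled["cutr"] + pooled["autr"]) >= min_reads
    ref_ratio = np.log2((pooled["autr"] + PSEUDOCOUNT)
                        / (pooled["cutr"] + PSEUDOCOUNT))

    per_gene = {}
    rows = []
    for group in n_cells.index:
        sub = agg.loc[group]
        ok = ((sub["cutr"] + sub["autr"]) >= min_reads) & ref_ok.reindex(sub.index, fill_value=False)
        ratio = np.log2((sub.loc[ok, "autr"] + PSEUDOCOUNT)
                        / (sub.loc[ok, "cutr"] + PSEUDOCOUNT))
        red = ratio - ref_ratio.reindex(ratio.index)
        per_gene[group] = red
        rows.append({"group": group, "n_cells": int(n_cells[group]),
                     "n_genes": int(ok.sum()), "median_red": float(red.median())})
    summary = pd.DataFrame(rows).set_index("group")
    summary["centered_red"] = normalize_red(summary["median_red"], mode=center)
    return ScsaapResult(assignments, pd.DataFrame(per_gene), summary)


# ---------------------------------------------------------------------------
# IO


def read_matrix(path: str | Path, barcodes: str | Path | None = None,
                features: str | Path | None = None) -> pd.DataFrame:
    """Read a cells x genes matrix from MTX (+ barcodes/features) or TSV."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        m = mmread(str(path)).tocsr()
        genes = [line.split("\t")[0].strip() for line in open(features)] if features else [
            f"g{i}" for i in range(m.shape[0])]
        cells = [line.strip() for line in open(barcodes)] if barcodes else [
            f"cell{i}" for i in range(m.shape[1])]
        # MTX convention: rows = features, columns = cells
        return pd.DataFrame(m.toarray().T, index=cells, columns=genes)
    return pd.read_csv(path, sep="\t", index_col=0)
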