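"""Shared statistical primitives.

Small wrappers around scipy used across the package: the exact 2x2 test,
Benjamini-Hochberg correction, pseudocounted log ratios, and the
bootstrap SEM of a median. Conventions enforced here:

* a pseudocount of 0.5 is added inside every log2 of a count ratio
  (never inside an exact-test table, which always sees raw counts);
* a 2x2 table with an all-zero row or column is uninformative and gets
  p = 1 rather than an error.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

#: pseudocount used inside every log2 count ratio
PSEUDOCOUNT = 0.5


def log2_ratio(num: float, den: float, pseudo: float = PSEUDOCOUNT) -> float:
    """log2((num + pseudo) / (den + pseudo))."""
    return float(np.log2((num + pseudo) / (den + pseudo)))


def fisher_pvalue(table) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table of raw counts.

    A table with a zero row or column margin carries no information about
    association and returns p = 1.0.
    """
    t = np.rint(np.asarray(table, dtype=float)).astype(np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def hypergeom_upper_tail(overlap: int, universe: int, term_size: int,
                         query_size: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(universe, term_size, query_size)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, term_size, query_size))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def bootstrap_sem_median(values, n_boot: int = 100, rng=None) -> float:
    """Bootstrap standard error of the median (n_boot resamples)."""
    rng = np.random.default_rng(rng)
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    return float(np.median(v[idx], axis=1).std(ddof=1))


def ranksum_pvalue(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p, with degenerate guard."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
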