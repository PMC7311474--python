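"""Independent brute-force oracles used by the tests.

Each oracle is a direct, unoptimized implementation of the stated rule
(enumeration, log-factorials, naive scans) and deliberately avoids the
code paths it is used to check.
"""
from __future__ import annotations

import math
from collections import defaultdict

_LG = math.lgamma


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums hypergeometric pmf over all tables with the same margins whose
    probability does not exceed the observed table's (with the standard
    1 + 1e-7 slack for floating-point ties).
    """
    r1, r2, m = a + b, c + d, a + c
    n_tot = r1 + r2
    if r1 == 0 or r2 == 0 or m == 0 or m == n_tot:
        return 1.0

    def logpmf(k: int) -> float:
        return (_LG(r1 + 1) - _LG(k + 1) - _LG(r1 - k + 1)
                + _LG(r2 + 1) - _LG(m - k + 1) - _LG(r2 - m + k + 1)
                - (_LG(n_tot + 1) - _LG(m + 1) - _LG(n_tot - m + 1)))

    lo, hi = max(0, m - r2), min(r1, m)
    p_obs = math.exp(logpmf(a))
    total = 0.0
    for k in range(lo, hi + 1):
        pk = math.exp(logpmf(k))
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def hypergeom_upper_tail(overlap: int, universe: int, term_size: int,
                         query_size: int) -> float:
    """P[X >= overlap] by direct summation of C(K,k)C(N-K,n-k)/C(N,n)."""
    def comb(n, k):
        if k < 0 or k > n:
            return 0.0
        return math.exp(_LG(n + 1) - _LG(k + 1) - _LG(n - k + 1))

    denom = comb(universe, query_size)
    total = 0.0
    for k in range(overlap, min(term_size, query_size) + 1):
        total += comb(term_size, k) * comb(universe - term_size, query_size - k)
    return min(total / denom, 1.0) if denom else 1.0


def greedy_cluster(positions: dict[int, int], strand: str, window: int = 24):
    """Reference greedy clustering: plain O(P*S) scan, no shortcuts.

    positions: position -> pooled count. Returns {representative:
    sorted members}.
    """
    orient = (lambda p: p) if strand == "+" else (lambda p: -p)
    order = sorted(positions, key=lambda p: (-positions[p], orient(p)))
    seeds: list[int] = []
    members: dict[int, list[int]] = {}
    for pos in order:
        candidates = [(abs(pos - s), orient(s), s) for s in seeds
                      if abs(pos - s) <= window]
        if not candidates:
            seeds.append(pos)
            members[pos] = [pos]
        else:
            _, _, s = min(candidates)
            members[s].append(pos)
    return {s: sorted(v) for s, v in members.items()}


def count_kmer_presence(sequences: list[str], kmer: str) -> int:
    """Naive scan: number of sequences containing the k-mer."""
    n = 0
    for seq in sequences:
        seq = seq.upper()
        found = False
        for i in range(len(seq) - len(kmer) + 1):
            if seq[i:i + len(kmer)] == kmer:
                found = True
                break
        n += found
    return n


def consensus_panel(study_tables: dict[str, dict[str, str]]) -> dict[str, str]:
    """Set-logic oracle for the marker panel rule: a gene is a marker of
    subtype S iff >=2 studies label it S and no study labels it anything
    else."""
    labels: dict[str, list[str]] = defaultdict(list)
    for table in study_tables.values():
        for gene, subtype in table.items():
            labels[gene].append(subtype)
    out = {}
    for gene, ls in labels.items():
        if len(ls) >= 2 and len(set(ls)) == 1:
            out[gene] = ls[0]
    return out


def go_filter(terms: dict[str, set], query: set, universe: set,
              max_term_size: int = 1000, overlap_frac: float = 0.75,
              pvalues: dict[str, float] | None = None):
    """Literal re-application of the GO filtering rules.

    Returns the ordered list of kept term ids. ``pvalues`` may supply
    per-term p-values (e.g. the implementation's, so that the filter
    logic is compared independently of float-level p ties); otherwise
    the enumeration oracle computes them.
    """
    scored = []
    for term_id in terms:
        genes = terms[term_id] & universe
        if not genes or len(genes) > max_term_size:
            continue
        overlap = len(genes & query)
        if pvalues is not None:
            p = pvalues[term_id]
        else:
            p = hypergeom_upper_tail(overlap, len(universe), len(genes),
                                     len(query))
        scored.append((p, -overlap, term_id, genes))
    scored.sort()
    kept = []
    kept_sets = []
    for p, _, term_id, genes in scored:
        if any(len(genes & k) / len(genes) > overlap_frac for k in kept_sets):
            continue
        kept.append(term_id)
        kept_sets.append(genes)
    return kept
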