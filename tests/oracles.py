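"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: enumeration,
per-bp set arithmetic, scipy graph matching and naive agglomeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching


def binomial_lower_tail_by_enumeration(p: float, m: int, n: int = 13) -> float:
    """P(X <= m) by summing the product weights of all 2^n outcome vectors."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=n):
        successes = sum(outcome)
        if successes <= m:
            total += p**successes * (1.0 - p) ** (n - successes)
    return total


def binomial_mass_by_enumeration(p: float, n: int = 13) -> np.ndarray:
    """Full pmf over 0..n successes via 2^n enumeration."""
    mass = np.zeros(n + 1)
    for outcome in itertools.product((0, 1), repeat=n):
        successes = sum(outcome)
        mass[successes] += p**successes * (1.0 - p) ** (n - successes)
    return mass


def max_matching_size(intervals_i, intervals_j) -> int:
    """Maximum bipartite matching size on the interval-overlap graph."""
    rows, cols = [], []
    for a, iv in enumerate(intervals_i):
        for b, jv in enumerate(intervals_j):
            if iv.chrom == jv.chrom and iv.start < jv.end and jv.start < iv.end:
                rows.append(a)
                cols.append(b)
    if not rows:
        return 0
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(intervals_i), len(intervals_j)),
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def covered_basepairs(intervals, chrom: str, length: int) -> set[int]:
    """Per-bp union of intervals on one arm (only for tiny toy arms)."""
    covered: set[int] = set()
    for iv in intervals:
        if iv.chrom == chrom:
            covered.update(range(iv.start, min(iv.end, length)))
    return covered


def average_linkage_heights(D: np.ndarray) -> list[float]:
    """Naive O(n^3) average-linkage agglomeration; returns merge heights."""
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights: list[float] = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


def contingency_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Independent 2x2 chi-square via scipy's contingency machinery."""
    from scipy.stats import chi2_contingency

    chi2, p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
    return float(chi2), float(p)
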