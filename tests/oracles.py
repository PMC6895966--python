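"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — exact rational arithmetic and
exhaustive enumeration — and independent of the code paths under test.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-sided Fisher p by exact enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {
        i: Fraction(comb(r1, i) * comb(n - r1, c1 - i), denom) for i in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by direct rational summation of the mass function."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)


def rank_sum_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group splits.

    Requires tie-free pooled values.  The two-sided p doubles the smaller
    tail (point mass included), clipped at 1.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = [
        sum(ranks[pooled[i]] for i in subset) - n * (n + 1) / 2
        for subset in itertools.combinations(range(n + m), n)
    ]
    total = len(us)
    le = sum(u <= u_obs for u in us)
    ge = sum(u >= u_obs for u in us)
    return min(1.0, 2 * min(le, ge) / total)


def signed_rank_two_sided(diffs) -> float:
    """Exact two-sided Wilcoxon signed-rank p by enumerating sign patterns.

    Requires non-zero, tie-free absolute differences.
    """
    diffs = [d for d in diffs if d != 0]
    n = len(diffs)
    absolute = sorted(abs(d) for d in diffs)
    assert len(set(absolute)) == n, "oracle requires tie-free |differences|"
    ranks = {v: i + 1 for i, v in enumerate(absolute)}
    w_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    ws = [
        sum(r for r, sign in zip(sorted(ranks.values()), signs) if sign)
        for signs in itertools.product([False, True], repeat=n)
    ]
    total = len(ws)
    le = sum(w <= w_obs for w in ws)
    ge = sum(w >= w_obs for w in ws)
    return min(1.0, 2 * min(le, ge) / total)


def bh_step_up(p_values) -> list[float]:
    """Textbook BH step-up computed with explicit sorting and monotonization."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [p_values[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = [0.0] * m
    for i, idx in enumerate(order):
        q[idx] = min(1.0, q_sorted[i])
    return q


def ward_merge_heights(points: np.ndarray) -> list[float]:
    """Heights of a greedy exhaustive Ward agglomeration (minimum variance increase).

    At every step all cluster pairs are scored from raw member coordinates:
    d(A, B) = sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||,
    the scaling under which two singletons merge at their Euclidean
    distance.  Returns the n-1 merge heights in merge order.
    """
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ca, cb = points[a].mean(axis=0), points[b].mean(axis=0)
                d = np.sqrt(
                    2.0 * len(a) * len(b) / (len(a) + len(b))
                ) * np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(float(d))
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def first_neighbor_expansion(seeds, edges) -> set:
    """Breadth-1 expansion oracle: seeds plus every node sharing an edge."""
    nodes = set(seeds)
    for a, b in edges:
        if a in seeds:
            nodes.add(b)
        if b in seeds:
            nodes.add(a)
    return nodes


def filter_failures(record) -> set:
    """Independent re-statement of the eight filter predicates (lenient mode,
    frequency-gated reading of rule six, missing population frequency = 0,
    missing dbSNP = absent)."""
    failed = set()
    vaf = record.tumor_vaf
    if vaf is None:
        vaf = record.tumor_alt_reads / record.tumor_depth if record.tumor_depth else 0.0
    if record.phred_quality is not None and record.phred_quality < 30:
        failed.add("R1")
    if record.strand_bias_p is not None and record.strand_bias_p < 0.01:
        failed.add("R2")
    if record.tumor_alt_reads < 7:
        failed.add("R3")
    if vaf < 0.05 and record.tumor_depth < 500:
        failed.add("R4")
    ra, aa = record.ref_allele.upper(), record.alt_allele.upper()
    is_ct_ga = (ra, aa) in {("C", "T"), ("G", "A")}
    if vaf < 0.10 and is_ct_ga:
        failed.add("R5")
    pop = max(record.pop_af_1kg_eur or 0.0, record.pop_af_exac_nfe or 0.0)
    if record.normal_depth is not None:
        if pop >= 0.01 and (bool(record.dbsnp_member) or record.normal_depth < 10):
            failed.add("R6")
        if record.normal_depth < 10:
            failed.add("R7")
    if record.normal_vaf is not None and record.normal_vaf >= 0.10:
        failed.add("R8")
    return failed
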