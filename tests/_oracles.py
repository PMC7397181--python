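"""Independent brute-force reference implementations used by the tests.

Each oracle re-derives an expected result from first principles (exhaustive
enumeration or definition-level set comparison) without sharing code with
the implementation it checks.
"""
from __future__ import annotations

import itertools
from math import comb

import numpy as np


# --- exact two-sided binomial by enumeration ----------------------------

def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    probs = [comb(n, i) * p0 ** i * (1 - p0) ** (n - i) for i in range(n + 1)]
    pk = probs[k]
    return min(1.0, sum(p for p in probs if p <= pk * (1 + 1e-12)))


# --- Fisher two-sided on a 2x2 by hypergeometric enumeration ------------

def fisher_two_sided(table) -> float:
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    pa = point(a)
    return min(1.0, sum(point(x) for x in range(lo, hi + 1)
                        if point(x) <= pa * (1 + 1e-12)))


# --- BH step-up by hand -------------------------------------------------

def bh_stepup(pvals):
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


# --- definition-level splice-event oracle for two-isoform genes ---------

def _junctions(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def oracle_event_kinds(exons_a, exons_b, strand: str) -> set[str]:
    """Event kinds present between two exon chains, derived directly from
    the definitions over junction sets (exhaustive comparison, no reuse of
    the classifier's rule engine)."""
    kinds: set[str] = set()
    ja, jb = set(_junctions(exons_a)), set(_junctions(exons_b))

    for x, y in ((exons_a, exons_b), (exons_b, exons_a)):
        jx, jy = set(_junctions(x)), set(_junctions(y))
        # retained intron: some junction of y falls strictly inside an
        # exon of x
        for (d, e) in jy:
            for (s, t) in x:
                if s < d and e < t:
                    kinds.add("RI")
        # skipped exon: an exon of x whose two flanking junctions exist in
        # x while y splices directly across
        for i in range(1, len(x) - 1):
            if (x[i - 1][1], x[i + 1][0]) in jy:
                kinds.add("SE")
        # mutually exclusive: internal exons of x and y, disjoint, with
        # identical outer flanking junction boundaries
        for i in range(1, len(x) - 1):
            for j in range(1, len(y) - 1):
                same_flanks = (x[i - 1][1] == y[j - 1][1]
                               and x[i + 1][0] == y[j + 1][0])
                disjoint = x[i][1] <= y[j][0] or y[j][1] <= x[i][0]
                if same_flanks and disjoint and x[i] != y[j]:
                    kinds.add("MX")
    # alternative splice sites: junction pairs sharing exactly one
    # boundary whose alternative exons overlap
    for (d1, a1), (d2, a2) in itertools.product(ja, jb):
        if (d1, a1) == (d2, a2):
            continue
        if d1 == d2 and a1 != a2:
            e1 = next(e for e in exons_a if e[0] == a1)
            e2 = next(e for e in exons_b if e[0] == a2)
            if e1[0] < e2[1] and e2[0] < e1[1]:
                kinds.add("A3" if strand == "+" else "A5")
        if a1 == a2 and d1 != d2:
            e1 = next(e for e in exons_a if e[1] == d1)
            e2 = next(e for e in exons_b if e[1] == d2)
            if e1[0] < e2[1] and e2[0] < e1[1]:
                kinds.add("A5" if strand == "+" else "A3")
    # alternative first/last exons: differing disjoint terminal exons
    # spliced to a common anchor
    if len(exons_a) >= 2 and len(exons_b) >= 2:
        fa, fb = exons_a[0], exons_b[0]
        if fa != fb and (fa[1] <= fb[0] or fb[1] <= fa[0]) \
                and _junctions(exons_a)[0][1] == _junctions(exons_b)[0][1]:
            kinds.add("AF" if strand == "+" else "AL")
        la, lb = exons_a[-1], exons_b[-1]
        if la != lb and (la[1] <= lb[0] or lb[1] <= la[0]) \
                and _junctions(exons_a)[-1][0] == _junctions(exons_b)[-1][0]:
            kinds.add("AL" if strand == "+" else "AF")
    return kinds


# --- PWM score distribution by full k-mer enumeration -------------------

def pwm_score_distribution_enum(matrix: np.ndarray):
    """(scores, probabilities) over all 4**k k-mers, uniform background."""
    with np.errstate(divide="ignore"):
        lo = np.log2(matrix / 0.25)
    k = matrix.shape[0]
    dist: dict[float, float] = {}
    for kmer in itertools.product(range(4), repeat=k):
        s = sum(lo[i, b] for i, b in enumerate(kmer))
        key = round(s, 9) if np.isfinite(s) else -np.inf
        dist[key] = dist.get(key, 0.0) + 0.25 ** k
    scores = np.array(sorted(dist))
    return scores, np.array([dist[s] for s in scores])
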