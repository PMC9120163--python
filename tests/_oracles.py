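"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: clustering by
pairwise union-find plus per-base counting, and exact rational
probabilities via math.comb / fractions.
"""

from fractions import Fraction
from math import comb


def brute_force_clusters(spans):
    """Connected components of the >=1-base-overlap graph via union-find,
    with per-base coverage heights counted base by base.

    Returns a sorted list of (start, end, n_reads, height).
    """
    n = len(spans)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            if s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(spans[i])
    out = []
    for members in groups.values():
        cs = min(s for s, _ in members)
        ce = max(e for _, e in members)
        height = 0
        for base in range(cs, ce):
            depth = sum(1 for s, e in members if s <= base < e)
            height = max(height, depth)
        out.append((cs, ce, len(members), height))
    return sorted(out)


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher's exact p by enumerating all tables with the
    observed margins, summing exact rational probabilities <= P(observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):  # table [[x, r1-x], [c1-x, r2-c1+x]]
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def hypergeom_upper_exact(k, K, n, N):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational sum."""
    denom = comb(N, n)
    total = sum(
        Fraction(comb(K, i) * comb(N - K, n - i), denom)
        for i in range(k, min(K, n) + 1)
    )
    return float(total)
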