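"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (exhaustive enumeration, exact
rational arithmetic) and shares no code with the implementation paths it
checks.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np


def set_partitions(items, k):
    """All partitions of ``items`` into exactly k non-empty blocks."""
    items = list(items)
    if k == 1:
        yield [items]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    # first joins an existing block of a (k)-partition of rest
    for part in set_partitions(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
    # first is a singleton next to a (k-1)-partition of rest
    for part in set_partitions(rest, k - 1):
        yield [[first]] + part


def within_ss(points, partition):
    """Total within-cluster sum of squared Euclidean distances to centroids."""
    total = 0.0
    for block in partition:
        pts = points[list(block)]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def best_k_partition(points, k):
    """Exhaustive minimum within-cluster-SS partition (as frozenset of frozensets)."""
    n = points.shape[0]
    best, best_ss = None, np.inf
    for part in set_partitions(range(n), k):
        ss = within_ss(points, part)
        if ss < best_ss - 1e-12:
            best_ss = ss
            best = frozenset(frozenset(b) for b in part)
    return best, best_ss


def labels_to_partition(labels):
    out = {}
    for i, l in enumerate(labels):
        out.setdefault(l, set()).add(i)
    return frozenset(frozenset(b) for b in out.values())


def dendrogram_nodes(merges, n):
    """The set of item sets represented by every node of a linkage tree."""
    nodes = {i: frozenset([i]) for i in range(n)}
    for step, (a, b, _, _) in enumerate(merges):
        nodes[n + step] = nodes[int(a)] | nodes[int(b)]
    return set(nodes.values())


def fisher_two_sided_exact(a, b, c, d):
    """Two-sided Fisher p by enumerating tables, multinomial probability form."""
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2

    def table_prob(x):  # x in the top-left cell
        y, z, w = r1 - x, c1 - x, n - r1 - c1 + x
        if min(y, z, w) < 0:
            return None
        num = (
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2)
        )
        den = (
            factorial(n)
            * factorial(x)
            * factorial(y)
            * factorial(z)
            * factorial(w)
        )
        return Fraction(num, den)

    p_obs = table_prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = table_prob(x)
        if p is not None and p <= p_obs * Fraction(10**7 + 1, 10**7):
            total += p
    return float(min(total, Fraction(1)))


def hypergeom_upper_exact(hits, set_size, universe, draw):
    """P(X >= hits) by direct summation of binomial-coefficient ratios."""
    from math import comb

    total = Fraction(0)
    for k in range(hits, min(set_size, draw) + 1):
        total += Fraction(
            comb(set_size, k) * comb(universe - set_size, draw - k),
            comb(universe, draw),
        )
    return float(min(total, Fraction(1)))


def ranksum_two_sided_exact(a, b):
    """Exact two-sided rank-sum p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = np.asarray(a + b, dtype=float)
    n, na = len(pooled), len(a)
    # mid-ranks
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = ranks[:na].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(n), na)]
    sums = np.asarray(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return float(min(1.0, 2.0 * min(lo, hi)))


def bh_step_up(p):
    """Direct BH step-up: p_(i) * m / i, cumulative minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        out[idx] = min(1.0, running)
    return out
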