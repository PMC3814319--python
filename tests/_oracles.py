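"""Independent reference computations shared by the test suite.

These deliberately use different code paths (plain-Python enumeration,
log-gamma identities) from the implementations they check.
"""

import itertools
import math


def ewens_conditional_exact(n: int, k: int) -> dict[tuple[int, ...], float]:
    """Exact Ewens configuration distribution conditional on k alleles:
    integer partitions of n into k parts weighted by 1/(prod_j j^{a_j} a_j!)
    (theta cancels conditionally)."""
    def partitions(n, k, mx):
        if k == 1:
            if n <= mx:
                yield (n,)
            return
        for first in range(min(n - k + 1, mx), 0, -1):
            for rest in partitions(n - first, k - 1, first):
                yield (first,) + rest

    weights = {}
    for part in partitions(n, k, n):
        a = {}
        for sz in part:
            a[sz] = a.get(sz, 0) + 1
        w = 1.0
        for j, aj in a.items():
            w /= (j ** aj) * math.factorial(aj)
        weights[part] = w
    tot = sum(weights.values())
    return {p: w / tot for p, w in weights.items()}


def brute_force_mst_weight(dist: dict[tuple[str, str], int], labels: list[str]) -> int:
    """Minimum spanning-tree weight by exhaustive enumeration (n <= 6)."""
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    edges = [(idx[a], idx[b], w) for (a, b), w in dist.items()]
    best = math.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x] = parent[parent[x]]
            return x

        ok = True
        for i, j, _ in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w for _, _, w in combo))
    return best
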