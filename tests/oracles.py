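"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exact integer enumeration, direct
definitional scans, union-find — and shares no code with the package.
"""

from __future__ import annotations

from math import comb


def exact_hypergeom_sf(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact integer enumeration of every outcome."""
    denom = comb(N, n)
    total = 0
    for j in range(k, min(n, K) + 1):
        total += comb(K, j) * comb(N - K, n - j)
    return total / denom


def exact_hypergeom_sf_all_k(n: int, K: int, N: int) -> list[float]:
    """P(X >= k) for every k in 0..min(n, K), by cumulative enumeration."""
    kmax = min(n, K)
    weights = [comb(K, j) * comb(N - K, n - j) for j in range(kmax + 1)]
    denom = comb(N, n)
    out = []
    tail = sum(weights)
    for j in range(kmax + 1):
        out.append(tail / denom)
        tail -= weights[j]
    return out


def bh_stepup(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg by the literal step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * pvalues[i] / rank_from_top)
        adjusted[i] = running_min
    return adjusted


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_lcc(nodes, edges):
    """Largest component via union-find; ties by smallest member symbol."""
    nodes = set(nodes) | {x for e in edges for x in e}
    uf = UnionFind(nodes)
    for u, v in edges:
        uf.union(u, v)
    comps: dict = {}
    for x in nodes:
        comps.setdefault(uf.find(x), set()).add(x)
    if not comps:
        return set(), set()
    max_size = max(len(c) for c in comps.values())
    best = min((c for c in comps.values() if len(c) == max_size), key=min)
    lcc_edges = {
        tuple(sorted(e)) for e in edges if e[0] in best and e[1] in best
    }
    return best, lcc_edges


def recount_modularity(nodes, edges, assignment) -> float:
    """Newman modularity by direct edge/degree recounting."""
    edges = [tuple(e) for e in edges]
    m = len(edges)
    if m == 0:
        return 0.0
    degree: dict = {x: 0 for x in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    modules = set(assignment[x] for x in nodes)
    q = 0.0
    for c in modules:
        members = {x for x in nodes if assignment[x] == c}
        e_c = sum(1 for u, v in edges if u in members and v in members)
        d_c = sum(degree[x] for x in members)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q
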