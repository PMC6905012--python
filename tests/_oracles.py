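"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: betweenness is
computed by enumerating every shortest path explicitly (exact rationals),
and Pearson's r by the two-pass textbook formula.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def brute_force_betweenness(adj: dict[str, set[str]]) -> dict[str, Fraction]:
    """Raw betweenness by explicit enumeration of all shortest paths.

    For every unordered pair (s, t), a breadth-first search from s builds
    the distance layering, then a depth-first walk backwards from t
    enumerates every shortest path; each interior node of each path
    collects 1/(number of shortest paths) for that pair.
    """
    nodes = sorted(adj)
    bc = {v: Fraction(0) for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            continue
        paths: list[list[str]] = []

        def walk(u: str, tail: list[str]) -> None:
            if u == s:
                paths.append(tail[::-1])
                return
            for w in adj[u]:
                if w in dist and dist[w] == dist[u] - 1:
                    walk(w, tail + [w])

        walk(t, [t])
        share = Fraction(1, len(paths))
        for p in paths:
            for v in p[1:-1]:
                bc[v] += share
    return bc


def normalized_brute_force_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    n = len(adj)
    raw = brute_force_betweenness(adj)
    if n < 3:
        return {v: 0.0 for v in raw}
    denom = Fraction((n - 1) * (n - 2), 2)
    return {v: float(b / denom) for v, b in raw.items()}


def textbook_pearson(x, y) -> float:
    """Two-pass product-moment formula, no shortcuts shared with the package."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def random_graph_adjacency(rng, n_nodes: int, p: float) -> dict[str, set[str]]:
    """Erdos-Renyi adjacency over string node names."""
    names = [f"n{i}" for i in range(n_nodes)]
    adj: dict[str, set[str]] = {v: set() for v in names}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < p:
                adj[names[i]].add(names[j])
                adj[names[j]].add(names[i])
    return adj
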