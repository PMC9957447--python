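"""Independent brute-force oracles used by the tests.

These deliberately avoid networkx/scipy graph routines so they can serve as
a second opinion on the implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(ell: int, k: int, L: int, n: int) -> Fraction:
    """P(X >= ell) for X ~ Hypergeom(n, L, k) by exact combinatorial sum."""
    total = comb(n, k)
    acc = 0
    for x in range(max(ell, 0), min(k, L) + 1):
        acc += comb(L, x) * comb(n - L, k - x)
    return Fraction(acc, total)


def brute_graph_summary(edges: list[tuple[str, str]]) -> dict:
    """Plain-python undirected-projection statistics of a directed edge list."""
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    nodes = sorted(adj)
    deg = {u: len(adj[u]) for u in nodes}

    # diameter of largest connected component by BFS from every node
    seen: set[str] = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in comp:
                        comp.add(w)
                        nxt.append(w)
            frontier = nxt
        seen |= comp
        components.append(comp)
    big = max(components, key=len)
    diameter = 0
    for src in big:
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        diameter = max(diameter, max(dist.values()))

    # mean local clustering
    cc = []
    for u in nodes:
        neigh = list(adj[u])
        d = len(neigh)
        if d < 2:
            cc.append(0.0)
            continue
        links = sum(
            1
            for i in range(d)
            for j in range(i + 1, d)
            if neigh[j] in adj[neigh[i]]
        )
        cc.append(2 * links / (d * (d - 1)))
    clustering = sum(cc) / len(cc)

    # Pearson correlation over both orientations of every undirected edge
    pairs = []
    und_edges = {tuple(sorted((u, v))) for u, v in edges}
    for u, v in und_edges:
        pairs.append((deg[u], deg[v]))
        pairs.append((deg[v], deg[u]))
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sx = (sum((x - mx) ** 2 for x in xs)) ** 0.5
    sy = (sum((y - my) ** 2 for y in ys)) ** 0.5
    if sx == 0 or sy == 0:
        assortativity = float("nan")
    else:
        cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        assortativity = cov / (sx * sy)

    return {
        "n_nodes": len(nodes),
        "mean_degree": sum(deg.values()) / len(nodes),
        "largest_degree": max(deg.values()),
        "diameter": diameter,
        "clustering_coefficient": clustering,
        "degree_coefficient": assortativity,
    }
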