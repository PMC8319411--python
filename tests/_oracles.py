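"""Brute-force reference implementations used only as test oracles.

Everything here is written from first-principles definitions (path
enumeration, triple counting, direct formulas) with no use of networkx, so
it stays independent of the implementations under test.
"""

from __future__ import annotations

import itertools
import math


def all_shortest_paths(nodes, adj, s, t):
    """All shortest simple paths s -> t by exhaustive DFS enumeration."""
    paths = []
    best = [math.inf]

    def dfs(path):
        u = path[-1]
        if len(path) - 1 > best[0]:
            return
        if u == t:
            if len(path) - 1 < best[0]:
                best[0] = len(path) - 1
                paths.clear()
            if len(path) - 1 == best[0]:
                paths.append(list(path))
            return
        for v in adj[u]:
            if v not in path:
                path.append(v)
                dfs(path)
                path.pop()

    dfs([s])
    return paths if paths else None


def _adj(nodes, edges):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bf_betweenness(nodes, edges):
    """Normalized betweenness centrality per node by path enumeration."""
    nodes = list(nodes)
    adj = _adj(nodes, edges)
    n = len(nodes)
    bc = {u: 0.0 for u in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(nodes, adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        for v in bc:
            bc[v] /= norm
    return bc


def bf_shortest_path_length(nodes, adj, s, t):
    paths = all_shortest_paths(nodes, adj, s, t)
    return (len(paths[0]) - 1) if paths else math.inf


def bf_harmonic_closeness(nodes, edges):
    nodes = list(nodes)
    adj = _adj(nodes, edges)
    n = len(nodes)
    out = {}
    for v in nodes:
        total = 0.0
        for u in nodes:
            if u == v:
                continue
            d = bf_shortest_path_length(nodes, adj, v, u)
            if math.isfinite(d) and d > 0:
                total += 1.0 / d
        out[v] = total / (n - 1) if n > 1 else 0.0
    return out


def bf_transitivity(nodes, edges):
    nodes = list(nodes)
    eset = {frozenset(e) for e in edges}
    triangles = sum(
        1 for a, b, c in itertools.combinations(nodes, 3)
        if frozenset((a, b)) in eset and frozenset((b, c)) in eset
        and frozenset((a, c)) in eset
    )
    deg = {u: 0 for u in nodes}
    for e in eset:
        a, b = tuple(e)
        deg[a] += 1
        deg[b] += 1
    triples = sum(d * (d - 1) // 2 for d in deg.values())
    return 3.0 * triangles / triples if triples else 0.0


def bf_local_clustering(nodes, edges):
    nodes = list(nodes)
    adj = _adj(nodes, edges)
    eset = {frozenset(e) for e in edges}
    out = {}
    for v in nodes:
        nb = list(adj[v])
        k = len(nb)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2)
            if frozenset((a, b)) in eset
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def bf_assortativity(nodes, edges):
    """Pearson correlation of degrees at edge endpoints, both orientations."""
    deg = {u: 0 for u in nodes}
    eset = {frozenset(e) for e in edges}
    for e in eset:
        a, b = tuple(e)
        deg[a] += 1
        deg[b] += 1
    xs, ys = [], []
    for e in eset:
        a, b = tuple(e)
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    n = len(xs)
    if n == 0:
        return math.nan
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def bf_bh(pvalues):
    """Quadratic-time Benjamini-Hochberg step-up from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for pos_i, i in enumerate(order):
        best = min(
            pvalues[order[pos_j]] * m / (pos_j + 1) for pos_j in range(pos_i, m)
        )
        q[i] = min(1.0, best)
    return q


def bf_anosim_r(dist, labels):
    """ANOSIM R from the definition: midranks of all pairwise distances."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [dist[i][j] for i, j in pairs]
    order = sorted(range(len(vals)), key=lambda k: vals[k])
    ranks = [0.0] * len(vals)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[k]]:
            j += 1
        midrank = (k + j) / 2.0 + 1.0
        for idx in order[k : j + 1]:
            ranks[idx] = midrank
        k = j + 1
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    rw = sum(within) / len(within)
    rb = sum(between) / len(between)
    return (rb - rw) / (n * (n - 1) / 4.0)
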