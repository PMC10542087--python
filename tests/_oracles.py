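"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (path enumeration, direct formulas)
and shares no code with the package implementation, so agreement is
evidence of correctness rather than of shared bugs.  Only viable for tiny
graphs (N <= 8).
"""

from __future__ import annotations

import numpy as np


def _simple_paths(adj, s, t):
    """All simple paths from s to t, by depth-first enumeration."""
    n = len(adj)
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nxt in range(n):
            if adj[node][nxt] and nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths


def _shortest_paths(adj, s, t):
    paths = _simple_paths(adj, s, t)
    if not paths:
        return np.inf, []
    d = min(len(p) - 1 for p in paths)
    return d, [p for p in paths if len(p) - 1 == d]


def oracle_global_and_nodal_efficiency(adj):
    n = len(adj)
    nodal = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j == i:
                continue
            d, _ = _shortest_paths(adj, i, j)
            if np.isfinite(d) and d > 0:
                acc += 1.0 / d
        nodal[i] = acc / (n - 1)
    return float(nodal.mean()), nodal


def oracle_metrics(adj):
    """degree, nodal/global efficiency, clustering, local efficiency,
    betweenness (normalised) by exhaustive path enumeration."""
    adj = np.asarray(adj, dtype=int)
    n = len(adj)
    degree = adj.sum(axis=1).astype(float)

    global_eff, nodal_eff = oracle_global_and_nodal_efficiency(adj)

    clustering = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(adj[a][b] for ai, a in enumerate(nb) for b in nb[ai + 1:])
        clustering[i] = 2.0 * links / (k * (k - 1))

    local_eff = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        ge, _ = oracle_global_and_nodal_efficiency(sub)
        local_eff[i] = ge

    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            d, sps = _shortest_paths(adj, s, t)
            if not sps:
                continue
            sigma = len(sps)
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in sps if i in p)
                betweenness[i] += through / sigma
    if n > 2:
        betweenness /= (n - 1) * (n - 2) / 2.0

    return {
        "degree": degree,
        "nodal_efficiency": nodal_eff,
        "global_efficiency": global_eff,
        "clustering_coefficient": clustering,
        "local_efficiency": local_eff,
        "betweenness": betweenness,
    }


def oracle_bh(pvals):
    """Benjamini-Hochberg step-up q-values by the direct formula."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


def oracle_pooled_t(x, y):
    """Pooled-variance two-sample t from first principles."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
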