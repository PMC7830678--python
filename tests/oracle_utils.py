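"""Independent brute-force oracles used across the test suite.

These deliberately avoid networkx/scipy/statsmodels code paths: distances
come from hand-written Floyd–Warshall, geodesic counts from a distance-
ordered DP, the hypergeometric tail from exact rational arithmetic, and
BH from the literal step-up recipe.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_centralities(nodes, edges):
    """All-pairs geodesic enumeration: DC, unnormalized BC, CC per node.

    Assumes a connected undirected simple graph.  Returns
    ``{node: (dc, bc, cc)}``.
    """
    nodes = list(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    INF = math.inf
    dist = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    adj = [[] for _ in range(n)]
    for u, v in edges:
        i, j = idx[u], idx[v]
        dist[i][j] = dist[j][i] = 1
        adj[i].append(j)
        adj[j].append(i)
    for k in range(n):
        dk = dist[k]
        for i in range(n):
            dik = dist[i][k]
            if dik == INF:
                continue
            di = dist[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt

    # geodesic counts sigma[s][t] by processing targets in distance order
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        order = sorted(range(n), key=lambda t: dist[s][t])
        sigma[s][s] = 1
        for t in order:
            if t == s:
                continue
            sigma[s][t] = sum(
                sigma[s][u] for u in adj[t] if dist[s][u] == dist[s][t] - 1
            )

    out = {}
    for v in range(n):
        dc = len(adj[v])
        bc = 0.0
        for s in range(n):
            if s == v:
                continue
            for t in range(s + 1, n):
                if t == v:
                    continue
                if dist[s][v] + dist[v][t] == dist[s][t]:
                    bc += sigma[s][v] * sigma[v][t] / sigma[s][t]
        total = sum(dist[v])
        cc = (n - 1) / total if total > 0 else 0.0
        out[nodes[v]] = (dc, bc, cc)
    return out


def oracle_hypergeom_tail(k, K, n, N):
    """Exact P(X >= k) by summing the PMF with rational arithmetic."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return total


def oracle_bh(pvalues):
    """Literal BH step-up: sort, scale by m/rank, cumulative min from the top."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
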