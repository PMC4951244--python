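"""Independent brute-force oracles shared by the test suite."""

import itertools


def brute_force_centrality(edges, nodes):
    """Independent all-pairs-shortest-path oracle for tiny graphs.

    Distances by Floyd-Warshall over an adjacency matrix; shortest-path
    counts by dynamic programming over increasing distance; betweenness as
    the pair-sum of sigma(s,v) * sigma(v,t) / sigma(s,t).
    """
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    INF = float("inf")
    dist = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    adj = [[False] * n for _ in range(n)]
    for a, b in edges:
        i, j = idx[a], idx[b]
        dist[i][j] = dist[j][i] = 1
        adj[i][j] = adj[j][i] = True
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    # sigma[s][t]: number of shortest s-t paths
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        sigma[s][s] = 1
        for d in range(1, n):
            for t in range(n):
                if dist[s][t] == d:
                    sigma[s][t] = sum(
                        sigma[s][u] for u in range(n) if adj[u][t] and dist[s][u] == d - 1
                    )
    result = {}
    for v in range(n):
        comp = [u for u in range(n) if dist[v][u] < INF]
        degree = sum(adj[v])
        btw = 0.0
        for s, t in itertools.combinations(range(n), 2):
            if s == v or t == v or dist[s][t] == INF:
                continue
            if dist[s][v] + dist[v][t] == dist[s][t]:
                btw += sigma[s][v] * sigma[v][t] / sigma[s][t]
        others = [dist[v][u] for u in comp if u != v]
        closeness = len(others) / sum(others) if others else 0.0
        ecc = max(others) if others else None
        result[nodes[v]] = (degree, btw, closeness, ecc)
    return result
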