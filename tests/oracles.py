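"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written by the most literal route
available (path enumeration, exhaustive permutation, truncated series,
hand-rolled running sums) and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb, factorial

import numpy as np


# -- screening ---------------------------------------------------------------

def adme_pass(rec) -> bool:
    """Literal re-statement of the screening cascade for one record."""
    vals = [rec.OB, rec.DL, rec.MW, rec.Hdon, rec.Hacc, rec.iLOGP, rec.GI]
    if any(v is None for v in vals):
        return False
    ok = rec.OB > 30
    ok = ok and str(rec.GI).strip().lower() == "high"
    ok = ok and rec.DL > 0.18
    ok = ok and rec.MW <= 500
    ok = ok and rec.Hdon <= 5
    ok = ok and rec.Hacc <= 10
    ok = ok and rec.iLOGP <= 5
    return ok


# -- graphs ------------------------------------------------------------------

def _bfs_dists(adj: dict, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def _adjdict(graph):
    return {v: sorted(graph[v]) for v in graph}


def brute_degree(graph):
    return {v: len(list(graph[v])) for v in graph}


def brute_betweenness(graph):
    """Path-enumeration betweenness (unnormalised, endpoints excluded)."""
    adj = _adjdict(graph)
    nodes = sorted(adj, key=str)
    bet = {v: 0.0 for v in nodes}

    def all_shortest_paths(s, t, dist):
        if t not in dist:
            return []
        paths = []

        def back(v, acc):
            if v == s:
                paths.append([s] + acc)
                return
            for w in adj[v]:
                if w in dist and dist[w] == dist[v] - 1:
                    back(w, [v] + acc)

        back(t, [])
        return paths

    for i, s in enumerate(nodes):
        dist = _bfs_dists(adj, s)
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t, dist)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bet[v] += 1.0 / len(paths)
    return bet


def brute_closeness(graph):
    adj = _adjdict(graph)
    out = {}
    for v in adj:
        dist = _bfs_dists(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_eigenvector(graph):
    """Shifted power iteration (A + I) from the uniform start vector.

    The +I shift guarantees convergence on bipartite graphs (whose
    adjacency spectrum is symmetric) without moving the eigenvectors.
    """
    nodes = list(graph.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b in graph.edges():
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
    v = np.ones(n) / np.sqrt(n)
    for _ in range(500_000):
        nxt = A @ v + v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.linalg.norm(nxt - v) < 1e-14:
            v = nxt
            break
        v = nxt
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return dict(zip(nodes, v))


def brute_lac(graph):
    out = {}
    for v in graph:
        nbrs = set(graph[v])
        if not nbrs:
            out[v] = 0.0
            continue
        total = 0
        for w in nbrs:
            total += sum(1 for u in graph[w] if u in nbrs)
        out[v] = total / len(nbrs)
    return out


def brute_network_centrality(graph):
    out = {v: 0.0 for v in graph}
    for v in graph:
        for w in graph[v]:
            denom = min(len(list(graph[v])) - 1, len(list(graph[w])) - 1)
            if denom <= 0:
                continue
            tri = sum(1 for u in graph[v] if graph.has_edge(u, w))
            out[v] += tri / denom
    return out


def brute_subgraph(graph, terms: int = 60):
    """Series-truncated matrix exponential diagonal."""
    nodes = list(graph.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b in graph.edges():
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
    acc = np.eye(n)
    power = np.eye(n)
    for k in range(1, terms + 1):
        power = power @ A
        acc = acc + power / factorial(k)
    return {v: acc[idx[v], idx[v]] for v in nodes}


def brute_information(graph):
    """Stephenson-Zelen information via effective resistances from the
    Laplacian pseudoinverse, per connected component."""
    import networkx as nx
    out = {}
    for comp in nx.connected_components(graph):
        comp = list(comp)
        n = len(comp)
        if n == 1:
            out[comp[0]] = 0.0
            continue
        idx = {v: i for i, v in enumerate(comp)}
        A = np.zeros((n, n))
        for a, b in graph.subgraph(comp).edges():
            A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
        L = np.diag(A.sum(axis=1)) - A
        Ld = np.linalg.pinv(L)
        for v in comp:
            i = idx[v]
            rsum = sum(Ld[i, i] + Ld[j, j] - 2 * Ld[i, j] for j in range(n))
            out[v] = n / rsum
    return out


BRUTE_ORACLES = {
    "degree": brute_degree,
    "betweenness": brute_betweenness,
    "closeness": brute_closeness,
    "eigenvector": brute_eigenvector,
    "lac": brute_lac,
    "network_c": brute_network_centrality,
    "subgraph": brute_subgraph,
    "information": brute_information,
}


# -- statistics --------------------------------------------------------------

def exact_wilcoxon_p(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.array(x + y)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    # average ranks over ties
    i = 0
    srt = pooled[order]
    while i < len(srt):
        j = i
        while j < len(srt) and srt[j] == srt[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n1 = len(x)
    obs = ranks[:n1].sum()
    mu = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


def hypergeom_tail(k, N, K, n) -> float:
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    denom = comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += comb(K, j) * comb(N - K, n - j)
    return total / denom


def ssgsea_running_sum(values, in_set, tau) -> float:
    """Literal step-by-step running-sum score for one sample.

    ``values`` are the expression values of all genes, ``in_set`` the
    membership flags.  Average ascending ranks over ties; walk in
    descending expression order; accumulate the difference between the
    normalised in-set weight CDF and the uniform out-of-set CDF.
    """
    values = list(map(float, values))
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    asc = sorted(range(n), key=lambda i: (values[i], i))
    rank = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and values[asc[j]] == values[asc[i]]:
            j += 1
        for t in range(i, j):
            rank[asc[t]] = (i + j + 1) / 2.0
        i = j
    w_total = sum(rank[g] ** tau for g in range(n) if in_set[g])
    m = sum(in_set)
    running_in = 0.0
    running_out = 0.0
    score = 0.0
    for g in order:
        if in_set[g]:
            running_in += (rank[g] ** tau) / w_total
        else:
            running_out += 1.0 / (n - m)
        score += running_in - running_out
    return score


def brute_logrank(time, event, group1) -> float:
    """(O-E)^2/V chi-square accumulated by a literal pass over event times."""
    time = list(map(float, time))
    event = list(map(int, event))
    group1 = list(map(bool, group1))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(t for t, e in zip(time, event) if e)):
        at_risk = [i for i in range(len(time)) if time[i] >= t]
        n = len(at_risk)
        n1 = sum(1 for i in at_risk if group1[i])
        d = sum(1 for i in at_risk if time[i] == t and event[i])
        d1 = sum(1 for i in at_risk if time[i] == t and event[i] and group1[i])
        if d and n > 1:
            o_minus_e += d1 - d * n1 / n
            var += d * n1 * (n - n1) * (n - d) / (n ** 2 * (n - 1))
    return o_minus_e ** 2 / var if var > 0 else 0.0
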