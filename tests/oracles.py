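"""Independent brute-force oracles for network statistics.

Everything here is deliberately naive (pure-Python loops, exhaustive
enumeration, Floyd–Warshall) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bfs_hops(A, source):
    """Directed hop distances from one node by breadth-first search."""
    n = len(A)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if A[u][v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def apl_oracle(A):
    """(mean finite hop distance over ordered pairs, number unreachable)."""
    n = len(A)
    total, count, unreachable = 0, 0, 0
    for s in range(n):
        dist = bfs_hops(A, s)
        for t in range(n):
            if t == s:
                continue
            if t in dist:
                total += dist[t]
                count += 1
            else:
                unreachable += 1
    return (total / count if count else float("nan")), unreachable


def clustering_oracle(A):
    n = len(A)
    acc = 0.0
    for i in range(n):
        nb = [j for j in range(n) if j != i and (A[i][j] or A[j][i])]
        k = len(nb)
        if k < 2:
            continue
        links = sum(A[u][v] for u in nb for v in nb if u != v)
        acc += links / (k * (k - 1))
    return acc / n if n else float("nan")


def triad_class_counts_oracle(A):
    """Counts of triads grouped by an independent canonical form.

    Returns ``{canonical_string: count}``; the canonical string is the
    lexicographically smallest flattened adjacency over the 6 relabelings.
    """
    n = len(A)
    out = {}
    for trip in itertools.combinations(range(n), 3):
        forms = []
        for p in itertools.permutations(trip):
            forms.append(
                "".join(
                    str(int(bool(A[p[a]][p[b]])))
                    for a in range(3)
                    for b in range(3)
                    if a != b
                )
            )
        canon = min(forms)
        out[canon] = out.get(canon, 0) + 1
    return out


def reciprocal_triangle_count_oracle(A):
    """Triples in which all six directed links are present."""
    n = len(A)
    c = 0
    for i, j, k in itertools.combinations(range(n), 3):
        if (
            A[i][j] and A[j][i] and A[i][k] and A[k][i] and A[j][k] and A[k][j]
        ):
            c += 1
    return c


def clique_count_oracle(A, size):
    """Complete-subgraph count by exhaustive subset enumeration."""
    n = len(A)
    if size > n:
        return 0
    if size == 1:
        return n
    c = 0
    for nodes in itertools.combinations(range(n), size):
        if all(A[u][v] and A[v][u] for u, v in itertools.combinations(nodes, 2)):
            c += 1
    return c


def reciprocity_oracle(A):
    n = len(A)
    uni = bi = 0
    for i in range(n):
        for j in range(i + 1, n):
            fwd, back = bool(A[i][j]), bool(A[j][i])
            if fwd and back:
                bi += 1
            elif fwd or back:
                uni += 1
    return uni, bi


def degree_oracle(A):
    n = len(A)
    k_in = sorted((sum(bool(A[i][j]) for i in range(n)) for j in range(n)), reverse=True)
    k_out = sorted((sum(bool(A[i][j]) for j in range(n)) for i in range(n)), reverse=True)
    return k_in, k_out


def floyd_warshall_oracle(w):
    """All-pairs shortest l = −ln w path lengths by Floyd–Warshall."""
    n = len(w)
    INF = math.inf
    d = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and w[i][j] > 0:
                d[i][j] = -math.log(w[i][j])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def enumerate_paths_oracle(w, source, target):
    """Shortest l-length over ALL simple paths (exhaustive DFS); inf if none."""
    n = len(w)
    best = math.inf

    def dfs(u, visited, acc):
        nonlocal best
        if u == target:
            best = min(best, acc)
            return
        for v in range(n):
            if v not in visited and w[u][v] > 0:
                dfs(v, visited | {v}, acc - math.log(w[u][v]))

    dfs(source, {source}, 0.0)
    return best


def global_efficiency_oracle(w):
    d = floyd_warshall_oracle(w)
    n = len(w)
    vals = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if d[i][j] == 0:
                continue  # zero-distance pairs excluded
            vals.append(1.0 / d[i][j] if math.isfinite(d[i][j]) else 0.0)
    return sum(vals) / len(vals) if vals else 0.0


def local_efficiency_oracle(w):
    n = len(w)
    acc = 0.0
    for i in range(n):
        nb = [j for j in range(n) if j != i and (w[i][j] > 0 or w[j][i] > 0)]
        k = len(nb)
        if k < 2:
            continue
        sub_nodes = [v for v in range(n) if v != i]
        idx = {v: a for a, v in enumerate(sub_nodes)}
        sub = [[w[u][v] for v in sub_nodes] for u in sub_nodes]
        d = floyd_warshall_oracle(sub)
        s = 0.0
        for u in nb:
            for v in nb:
                if u == v:
                    continue
                duv = d[idx[u]][idx[v]]
                if math.isfinite(duv) and duv > 0:
                    s += 1.0 / duv
        acc += s / (k * (k - 1))
    return acc / n if n else float("nan")


def brute_projectome_oracle(synapses, labels):
    """Direct per-neuron summation of in⊗out fraction matrices."""
    idx = {l: k for k, l in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    for nid in sorted(set(synapses["neuron_id"])):
        rows = synapses[synapses["neuron_id"] == nid]
        inc = np.zeros(n)
        outc = np.zeros(n)
        for _, r in rows.iterrows():
            if r["role"] == "post":
                inc[idx[r["region"]]] += 1
            else:
                outc[idx[r["region"]]] += 1
        if inc.sum() == 0 or outc.sum() == 0:
            continue
        W += np.outer(inc / inc.sum(), outc / outc.sum())
    return W
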