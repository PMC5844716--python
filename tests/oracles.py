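"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the libraries)
used by the package: betweenness by explicit geodesic enumeration, k-core by
literal iterative pruning, Fisher by summing hypergeometric point masses,
and BH by the textbook step-up recursion.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_betweenness(nodes, edges, directed: bool) -> dict:
    """Normalized betweenness via explicit enumeration of all geodesics."""
    nodes = list(nodes)
    adj: dict = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        if not directed:
            adj[v].add(u)

    def all_shortest_paths(s, t):
        # BFS layering, then DFS back-tracking to enumerate geodesics
        if s == t:
            return []
        dist = {s: 0}
        parents: dict = {s: []}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        parents[w] = [u]
                        nxt.append(w)
                    elif dist[w] == dist[u] + 1:
                        parents[w].append(u)
            frontier = nxt
        if t not in dist:
            return []
        paths = []

        def back(node, acc):
            if node == s:
                paths.append([s, *reversed(acc)])
                return
            for p in parents[node]:
                back(p, acc + [node])

        back(t, [])
        return paths

    score = {u: 0.0 for u in nodes}
    for s, t in itertools.permutations(nodes, 2):
        if not directed and s > t:
            continue
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for path in paths:
            for inner in path[1:-1]:
                score[inner] += 1.0 / len(paths)
    n = len(nodes)
    if n < 3:
        return {u: 0.0 for u in nodes}
    norm = (n - 1) * (n - 2) if directed else (n - 1) * (n - 2) / 2
    return {u: score[u] / norm for u in nodes}


def brute_force_k_core(nodes, edges) -> dict:
    """Core index by literal iterative pruning of an undirected simple graph."""
    nodes = set(nodes)
    neighbor: dict = {u: set() for u in nodes}
    for u, v in edges:
        if u != v:
            neighbor[u].add(v)
            neighbor[v].add(u)
    core = {u: 0 for u in nodes}
    k = 1
    alive = set(nodes)
    while alive:
        pruned = True
        while pruned:
            pruned = False
            for u in sorted(alive):
                if len(neighbor[u] & alive) < k:
                    alive.discard(u)
                    pruned = True
        for u in alive:
            core[u] = k
        k += 1
    return core


def brute_force_fisher(n_f: int, n: int, N_f: int, N: int) -> float:
    """P(X >= n_f) by summing hypergeometric point masses exactly."""
    total = comb(N, N_f)
    upper = min(n, N_f)
    acc = 0
    for x in range(n_f, upper + 1):
        acc += comb(n, x) * comb(N - n, N_f - x)
    return acc / total


def step_up_bh(p_values) -> np.ndarray:
    """Textbook BH: q_(i) = min_{j>=i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = running
    return q
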