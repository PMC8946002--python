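"""Brute-force reference implementations used only by the test suite.

Everything here is deliberately naive — exhaustive enumeration or direct
formula evaluation in pure Python — and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- shortest paths ---------------------------------------------------------

def shortest_path_lengths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/w distances by enumerating simple paths."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)

    def extend(path, dist):
        last = path[-1]
        D[path[0], last] = min(D[path[0], last], dist)
        for nxt in range(n):
            if nxt not in path and W[last, nxt] > 0:
                extend(path + [nxt], dist + 1.0 / W[last, nxt])

    for start in range(n):
        extend([start], 0.0)
    return D


def char_path_length(W: np.ndarray) -> float:
    D = shortest_path_lengths(W)
    n = W.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and math.isfinite(D[i, j])]
    return float(np.mean(vals))


# -- clustering -------------------------------------------------------------

def binary_clustering(A: np.ndarray) -> float:
    """Mean binary clustering coefficient by triangle counting."""
    n = A.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if A[a, b]
        )
        cs.append(2 * links / (k * (k - 1)))
    return float(np.mean(cs))


def weighted_clustering_triple(W: np.ndarray) -> float:
    """Direct triple-sum evaluation of the weighted clustering ratio."""
    n = W.shape[0]
    cs = []
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for k in range(n):
                if j == k or j == i or k == i:
                    continue
                num += W[i, j] * W[j, k] * W[k, i]
                den += W[i, j] * W[k, i]
        cs.append(num / den if den > 0 else 0.0)
    return float(np.mean(cs))


# -- spanning trees ---------------------------------------------------------

def _tree_from_pruefer(seq: tuple[int, ...], n: int) -> list[tuple[int, int]]:
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((leaf, v))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    last = [v for v in range(n) if degree[v] == 1]
    edges.append((last[0], last[1]))
    return edges


def all_spanning_trees(n: int):
    """Every labeled spanning tree on n nodes via Pruefer sequences."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield _tree_from_pruefer(seq, n)


def random_tree(rng: np.random.Generator, n: int) -> list[tuple[int, int]]:
    """Uniform random labeled tree from a random Pruefer sequence."""
    if n == 2:
        return [(0, 1)]
    seq = tuple(int(v) for v in rng.integers(0, n, size=n - 2))
    return _tree_from_pruefer(seq, n)


def max_spanning_tree_weight(W: np.ndarray) -> float:
    """Maximum total weight over all spanning trees with positive edges."""
    n = W.shape[0]
    best = -np.inf
    for edges in all_spanning_trees(n):
        if all(W[i, j] > 0 for i, j in edges):
            best = max(best, sum(W[i, j] for i, j in edges))
    return float(best)


# -- tree metrics -----------------------------------------------------------

def tree_metrics(edges: list[tuple[int, int]], n: int):
    """(bc_max, diameter, eccentricity, leaf) by BFS + path enumeration."""
    adj = {v: [] for v in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)

    def bfs(src):
        dist = {src: 0}
        parent = {src: None}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            frontier = nxt
        return dist, parent

    M = n - 1
    ecc = []
    through = {v: 0 for v in range(n)}
    dists = {}
    for s in range(n):
        dist, parent = bfs(s)
        dists[s] = dist
        ecc.append(max(dist.values()))
        for t in range(n):
            if t <= s:
                continue
            node = parent[t]
            while node is not None and node != s:
                through[node] += 1
                node = parent[node]
    diameter = max(ecc) / M
    eccentricity = float(np.mean(ecc)) / M
    leaf = sum(1 for v in range(n) if len(adj[v]) == 1) / M
    denom = (n - 1) * (n - 2) / 2
    bc_max = max(through.values()) / denom
    return bc_max, diameter, eccentricity, leaf


# -- modularity -------------------------------------------------------------

def set_partitions(items: list[int]):
    """All set partitions (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1:]
        yield [[first]] + part


def modularity_q(W: np.ndarray, partition: list[list[int]]) -> float:
    m2 = W.sum()  # 2m
    q = 0.0
    for block in partition:
        idx = np.array(block)
        e_c = W[np.ix_(idx, idx)].sum()  # 2 * within weight
        d_c = W[idx, :].sum()
        q += e_c / m2 - (d_c / m2) ** 2
    return float(q)


def best_modularity(W: np.ndarray) -> float:
    n = W.shape[0]
    return max(
        modularity_q(W, part) for part in set_partitions(list(range(n)))
    )


# -- rank-sum ---------------------------------------------------------------

def mannwhitney_u(a, b) -> float:
    return float(sum(
        (x > y) + 0.5 * (x == y) for x in a for y in b
    ))


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    u_obs = mannwhitney_u(a, b)
    us = [
        mannwhitney_u([pooled[i] for i in comb],
                      [pooled[i] for i in range(len(pooled)) if i not in comb])
        for comb in itertools.combinations(range(len(pooled)), na)
    ]
    n_tot = len(us)
    lo = sum(u <= u_obs for u in us) / n_tot
    hi = sum(u >= u_obs for u in us) / n_tot
    return min(1.0, 2 * min(lo, hi))


# -- misc -------------------------------------------------------------------

def random_weighted_graph(rng: np.random.Generator, n: int,
                          density: float = 1.0, low: float = 0.05,
                          high: float = 1.0) -> np.ndarray:
    """Random symmetric weight matrix; edges present with given density."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(low, high)
    return W
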